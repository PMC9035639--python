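"""Data/model-spec loading, result serialization, and run manifests.

Data are plain CSV with a header row; the model specification is a small
YAML (or JSON) document naming the response column, the predictor blocks,
and the component-level terms::

    response: y
    blocks:
      exposure: [age_cig, age_alc, age_mj]
      mental:   [distress, impair]
    terms:
      - linear:exposure
      - linear:mental
      - interaction:exposure*mental

Estimator results serialize to JSON; study grids serialize to tidy CSV.
A run manifest (JSON) records enough to replay any command: the command
line, configuration echo, seeds, timestamps, package version, and SHA-256
digests of the input files.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import BlockSpec, ERAError, ModelSpec, Term
from .resampling import EstimatorResult
from .simulation import StudyResult

__all__ = [
    "Dataset",
    "RunManifest",
    "parse_term",
    "load_model_spec",
    "load_dataset",
    "write_results",
    "read_results",
    "write_study",
    "make_manifest",
]


@dataclass
class Dataset:
    """A validated observation table split into response and predictors."""

    frame: pd.DataFrame
    response: str
    predictors: list[str]
    note: str = ""

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.response].to_numpy(dtype=float)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.predictors].to_numpy(dtype=float)

    @property
    def n_obs(self) -> int:
        return len(self.frame)


def parse_term(text: str, block_spec: BlockSpec) -> Term:
    """Parse ``"linear:blockA"`` / ``"interaction:blockA*blockB"`` /
    ``"quadratic:blockA"`` into a :class:`Term`."""
    try:
        kind, rest = text.split(":", 1)
    except ValueError:
        raise ERAError(f"malformed term {text!r}; expected 'kind:block'") from None
    kind = kind.strip()
    if kind == "interaction":
        parts = [p.strip() for p in rest.split("*")]
        if len(parts) != 2:
            raise ERAError(f"interaction term {text!r} must name two blocks joined by '*'")
        return Term("interaction", parts[0], parts[1])
    if kind in ("linear", "quadratic"):
        return Term(kind, rest.strip())
    raise ERAError(f"unknown term kind {kind!r} in {text!r}")


def load_model_spec(path: str | Path) -> tuple[ModelSpec, str, list[str]]:
    """Load a model-spec file.

    Returns ``(spec, response_column, predictor_columns)`` where the
    predictor columns are ordered block by block and the spec's indices
    refer to that ordering.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)  # JSON is a YAML subset
    if not isinstance(doc, dict):
        raise ERAError(f"{path}: model spec must be a mapping")
    for key in ("response", "blocks", "terms"):
        if key not in doc:
            raise ERAError(f"{path}: missing required key {key!r}")
    response = str(doc["response"])
    blocks_doc = doc["blocks"]
    if not isinstance(blocks_doc, dict) or not blocks_doc:
        raise ERAError(f"{path}: 'blocks' must be a non-empty mapping")
    predictor_cols: list[str] = []
    blocks = []
    for name, cols in blocks_doc.items():
        cols = [str(c) for c in cols]
        idx = []
        for c in cols:
            if c in predictor_cols:
                raise ERAError(f"{path}: column {c!r} assigned to more than one block")
            predictor_cols.append(c)
            idx.append(len(predictor_cols) - 1)
        blocks.append((str(name), idx))
    block_spec = BlockSpec(blocks)
    terms = [parse_term(str(t), block_spec) for t in doc["terms"]]
    return ModelSpec(block_spec, terms), response, predictor_cols


def load_dataset(
    path: str | Path, response: str, predictors: list[str], note: str = ""
) -> Dataset:
    """Load and validate a CSV: required columns present, numeric, no NAs."""
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ERAError(f"{path}: no data rows")
    needed = [response, *predictors]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ERAError(f"{path}: missing column(s) {missing}")
    frame = frame[needed]
    for col in needed:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals.isna()].tolist()
        if bad:
            raise ERAError(
                f"{path}: column {col!r} has missing or non-numeric values at row(s) {bad[:10]}"
            )
        frame[col] = vals.astype(float)
    return Dataset(frame=frame, response=response, predictors=list(predictors), note=note)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def write_results(results: EstimatorResult | list[EstimatorResult], path: str | Path) -> None:
    """Serialize estimator result(s) to JSON (lossless round trip)."""
    path = Path(path)
    if isinstance(results, EstimatorResult):
        payload = results.to_dict()
    else:
        payload = [r.to_dict() for r in results]
    doc = {"software": {"name": "eracv", "version": __version__}, "results": payload}
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_results(path: str | Path) -> list[EstimatorResult]:
    """Read back estimator results written by :func:`write_results`."""
    with open(path) as fh:
        doc = json.load(fh)
    payload = doc["results"]
    if isinstance(payload, dict):
        payload = [payload]
    out = []
    for d in payload:
        out.append(
            EstimatorResult(
                method=d["method"],
                value=float(d["value"]),
                settings=d.get("settings", {}),
                per_resample=None
                if d.get("per_resample") is None
                else np.asarray(d["per_resample"], dtype=float),
                auxiliary=d.get("auxiliary", {}),
                n_terms=d.get("n_terms"),
            )
        )
    return out


def write_study(result: StudyResult, out_dir: str | Path) -> dict[str, Path]:
    """Write a study's tidy CSVs (summary, per-rep, selections) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    result.summary.to_csv(out_dir / "summary.csv", index=False)
    paths["summary"] = out_dir / "summary.csv"
    result.per_rep.to_csv(out_dir / "per_rep.csv", index=False)
    paths["per_rep"] = out_dir / "per_rep.csv"
    if result.selections is not None:
        result.selections.to_csv(out_dir / "selections.csv", index=False)
        paths["selections"] = out_dir / "selections.csv"
    return paths


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Everything needed to re-run a command identically."""

    command: str
    config: dict
    seeds: dict
    timestamp: str
    version: str
    input_digests: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "config": self.config,
            "seeds": self.seeds,
            "timestamp": self.timestamp,
            "version": self.version,
            "input_digests": self.input_digests,
        }

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def make_manifest(command: str, config: dict, seeds: dict, inputs: list[str | Path] = ()) -> RunManifest:
    return RunManifest(
        command=command,
        config=config,
        seeds=seeds,
        timestamp=datetime.now(timezone.utc).isoformat(),
        version=__version__,
        input_digests={str(p): _sha256(Path(p)) for p in inputs},
    )
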