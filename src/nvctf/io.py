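"""Round-trippable file formats: trace CSVs, kernel JSON, trial manifests.

Traces travel as two-column delimited text with a required header
(``time_s,value``); trial metadata lives in a JSON sidecar; fitted kernels
are serialized as JSON objects carrying the four parameters, the signal
kinds they link, the stimulus label, and fit provenance (seed, config
hash).  All numeric output uses 12 significant digits so write-then-read
is an identity at that precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .fit import FitConfig
from .kernel import TFParams
from .signals import RawTrace, SignalKind, UniformSeries
from .trials import StimulusInfo, TrialRecord

__all__ = [
    "read_series",
    "write_series",
    "read_tf",
    "write_tf",
    "read_trial",
    "read_manifest",
    "config_hash",
]

_COLUMNS = ("time_s", "value")


def read_series(path: str | Path, kind: SignalKind = SignalKind.GENERIC) -> RawTrace:
    """Parse a two-column trace CSV/TSV into a validated raw trace."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # malformed file
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; header must be time_s,value")
    for col in _COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            # +2: one for the header, one for 1-based line numbers
            lines = (np.flatnonzero(coerced.isna().to_numpy()) + 2).tolist()
            raise ParseError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        df[col] = coerced
    times = df["time_s"].to_numpy(float)
    if not np.all(np.diff(times) > 0):
        idx = int(np.flatnonzero(np.diff(times) <= 0)[0])
        raise ParseError(f"{path}: times not strictly increasing at line {idx + 3}")
    return RawTrace(times, df["value"].to_numpy(float), kind)


def write_series(series: UniformSeries | RawTrace, path: str | Path) -> None:
    """Write a series as time_s,value CSV with 12 significant digits."""
    times = series.times
    pd.DataFrame({"time_s": times, "value": series.values}).to_csv(
        path, index=False, float_format="%.12g"
    )


def config_hash(config: FitConfig) -> str:
    payload = asdict(config)
    payload["initial_params"] = asdict(config.initial_params)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_tf(
    params: TFParams,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Serialize a fitted kernel with its provenance metadata."""
    doc = {"p1": params.p1, "p2": params.p2, "p3": params.p3, "p4": params.p4}
    doc.update(metadata or {})
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_tf(path: str | Path) -> tuple[TFParams, dict]:
    doc = json.loads(Path(path).read_text())
    missing = [k for k in ("p1", "p2", "p3", "p4") if k not in doc]
    if missing:
        raise ParseError(f"{path}: missing kernel field(s) {missing}")
    params = TFParams(*(float(doc.pop(k)) for k in ("p1", "p2", "p3", "p4")))
    return params, doc


def read_trial(
    from_path: str | Path, to_path: str | Path, meta_path: str | Path,
    subject_id: str | None = None,
) -> TrialRecord:
    """Assemble a trial from two trace CSVs and a metadata sidecar.

    The sidecar is JSON with stimulus_onset_s, stimulus_duration_s,
    acquisition_len_s, and optional odor/concentration/kind fields.  Traces
    are returned on their native grids; preprocessing (interpolation,
    baseline, window cut) is the caller's pipeline.
    """
    meta = json.loads(Path(meta_path).read_text())
    for key in ("stimulus_onset_s", "stimulus_duration_s", "acquisition_len_s"):
        if key not in meta:
            raise ParseError(f"{meta_path}: missing metadata field {key!r}")
    from .signals import interpolate_uniform

    from_kind = SignalKind(meta.get("from_kind", "calcium"))
    to_kind = SignalKind(meta.get("to_kind", "generic"))
    from_trace = read_series(from_path, from_kind)
    to_trace = read_series(to_path, to_kind)
    dt_from = float(meta.get("dt_from_s", 0.05))
    dt_to = float(meta.get("dt_to_s", 0.05))
    return TrialRecord(
        subject_id=subject_id or Path(meta_path).stem,
        from_sig=interpolate_uniform(from_trace, dt_from),
        to_sig=interpolate_uniform(to_trace, dt_to),
        stimulus=StimulusInfo(
            float(meta["stimulus_onset_s"]),
            float(meta["stimulus_duration_s"]),
            str(meta.get("odor", "")),
        ),
        acquisition_len=float(meta["acquisition_len_s"]),
    )


def read_manifest(path: str | Path) -> list[TrialRecord]:
    """Load a cohort manifest: JSON list of {id, from, to, meta} entries."""
    path = Path(path)
    doc = json.loads(path.read_text())
    entries = doc["subjects"] if isinstance(doc, dict) else doc
    ids = [e.get("id") for e in entries]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate subject ids")
    base = path.parent
    trials = []
    for e in entries:
        for key in ("from", "to", "meta"):
            if key not in e:
                raise ParseError(f"{path}: subject entry missing {key!r}")
            if not (base / e[key]).exists():
                raise ParseError(f"{path}: referenced path {e[key]!r} does not exist")
        trials.append(
            read_trial(base / e["from"], base / e["to"], base / e["meta"], e.get("id"))
        )
    return trials
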