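"""Plain-text file formats: SAXS .dat, ITC CSV and JSON fit reports.

SAXS curves are ATSAS-style whitespace tables ``q I [sigma]`` with ``#``
comments.  ITC titrations are CSV with a ``#key=value`` metadata block.
Numeric output uses repr-faithful precision; rounding happens only in
console display.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from coopfold.itc_binding import (
    IsothermFit,
    TitrationExperiment,
    TitrationProtocol,
)
from coopfold.saxs_analysis.profiles import ScatteringProfile

__all__ = [
    "read_saxs_dat",
    "write_saxs_dat",
    "read_itc_csv",
    "write_itc_csv",
    "write_fit_report",
]

logger = logging.getLogger("coopfold.io")

_ITC_REQUIRED_KEYS = ("cell_volume_uL", "cell_conc_M", "syringe_conc_M")


# ---------------------------------------------------------------------------
# SAXS .dat
# ---------------------------------------------------------------------------

def read_saxs_dat(path: str | Path) -> ScatteringProfile:
    """Read a 2- or 3-column SAXS curve; synthesizes sigma when absent."""
    path = Path(path)
    comments: list[str] = []
    q, i, s = [], [], []
    n_cols = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line[1:].strip())
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            try:
                values = [float(x) for x in fields]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row: {line!r}") from exc
            if n_cols is None:
                n_cols = len(fields)
            elif len(fields) != n_cols:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            q.append(values[0])
            i.append(values[1])
            if n_cols == 3:
                s.append(values[2])
    if not q:
        raise ValueError(f"{path}: no data rows")
    q_arr = np.asarray(q)
    if np.any(np.diff(q_arr) <= 0):
        raise ValueError(f"{path}: q must be strictly increasing")
    sigma = np.asarray(s) if s else None
    if sigma is None:
        logger.warning("%s: no sigma column; synthesizing sigma = 1%% of I", path)
        sigma = np.maximum(0.01 * np.abs(np.asarray(i)), 1e-12)
    return ScatteringProfile(
        q=q_arr, i=np.asarray(i), sigma=sigma, comments=tuple(comments)
    )


def write_saxs_dat(profile: ScatteringProfile, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# {c}" for c in profile.comments]
    sigma = profile.sigma
    for k in range(len(profile)):
        if sigma is None:
            lines.append(f"{float(profile.q[k])!r} {float(profile.i[k])!r}")
        else:
            lines.append(
                f"{float(profile.q[k])!r} {float(profile.i[k])!r} "
                f"{float(sigma[k])!r}"
            )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ITC CSV
# ---------------------------------------------------------------------------

def read_itc_csv(path: str | Path) -> TitrationExperiment:
    """Read an ITC titration CSV with its ``#key=value`` metadata block."""
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, sep, value = line[1:].partition("=")
                if sep:
                    meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = [h.strip() for h in line.split(",")]
                continue
            fields = line.split(",")
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row: {line!r}") from exc
    missing = [k for k in _ITC_REQUIRED_KEYS if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing metadata keys: {missing}")
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    expected = {"injection", "volume_uL", "ndh_kcal_per_mol"}
    if not expected.issubset(header):
        raise ValueError(f"{path}: header must contain {sorted(expected)}")
    col = {name: k for k, name in enumerate(header)}
    volumes = [r[col["volume_uL"]] for r in rows]
    ndh = [r[col["ndh_kcal_per_mol"]] for r in rows]
    sigma = None
    if "sigma" in col:
        sigma = tuple(r[col["sigma"]] for r in rows)
    protocol = TitrationProtocol(
        cell_volume_ul=float(meta["cell_volume_uL"]),
        cell_conc=float(meta["cell_conc_M"]),
        syringe_conc=float(meta["syringe_conc_M"]),
        injection_volumes_ul=tuple(volumes),
        temperature_c=float(meta.get("temperature_C", 25.0)),
    )
    seed = int(meta["seed"]) if "seed" in meta else None
    return TitrationExperiment(protocol=protocol, ndh=tuple(ndh), sigma=sigma, seed=seed)


def write_itc_csv(
    exp: TitrationExperiment, path: str | Path, extra_meta: dict | None = None
) -> None:
    path = Path(path)
    proto = exp.protocol
    meta = {
        "cell_volume_uL": repr(proto.cell_volume_ul),
        "cell_conc_M": repr(proto.cell_conc),
        "syringe_conc_M": repr(proto.syringe_conc),
        "temperature_C": repr(proto.temperature_c),
    }
    if exp.seed is not None:
        meta["seed"] = str(exp.seed)
    if extra_meta:
        meta.update({k: str(v) for k, v in extra_meta.items()})
    lines = [f"#{k}={v}" for k, v in meta.items()]
    cols = "injection,volume_uL,ndh_kcal_per_mol"
    if exp.sigma is not None:
        cols += ",sigma"
    lines.append(cols)
    for k, (dv, h) in enumerate(zip(proto.injection_volumes_ul, exp.ndh), start=1):
        row = f"{k},{dv!r},{h!r}"
        if exp.sigma is not None:
            row += f",{exp.sigma[k - 1]!r}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def write_fit_report(
    fit: IsothermFit, path: str | Path, metadata: dict | None = None
) -> None:
    """JSON fit report: parameters, errors, convergence and residual RMS."""
    payload = fit.to_dict()
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
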