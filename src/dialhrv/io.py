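"""Readers and writers for the plain-text input dialects.

RR files: one interval in milliseconds per line; blank lines and lines
starting with ``#`` are ignored.  The Polar-HRM-style dialect is also
accepted: a file containing bracketed section headers has its intervals
read from the lines following ``[HRData]``.

BP CSV: ``subject,t_min,sbp,dbp`` rows, nominally eight readings per
subject (fewer are accepted with a warning — sessions shorter than four
hours have fewer readings).  Covariates CSV:
``subject,filtered_volume_ml,urea_mg_dl[,group_truth]``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .series import BPSession, RRSeries, RR_MAX_MS, RR_MIN_MS, SBP_MAX, SBP_MIN

__all__ = ["read_rr_file", "read_bp_csv", "read_covariates_csv"]


def read_rr_file(path: str | Path, strict: bool = True) -> RRSeries:
    """Read a tachogram from a plain-text or Polar-HRM-style file.

    Out-of-range or non-numeric rows raise a ValueError naming the
    offending line numbers (``strict=True``) or are skipped with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    start = 0
    if any(ln.strip().startswith("[") for ln in lines):
        # Polar-HRM dialect: intervals listed after the [HRData] header
        for i, ln in enumerate(lines):
            if ln.strip().lower() == "[hrdata]":
                start = i + 1
                break
        else:
            raise ValueError(f"{path}: sectioned file without an [HRData] section")

    values: list[float] = []
    bad: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        ln = raw.strip()
        if not ln or ln.startswith("#"):
            continue
        if ln.startswith("[") and start > 0:
            break  # next section
        try:
            v = float(ln.split()[0])
        except ValueError:
            bad.append((lineno, f"not a number: {ln!r}"))
            continue
        if not RR_MIN_MS < v < RR_MAX_MS:
            bad.append((lineno, f"interval {v:g} ms outside "
                                f"({RR_MIN_MS:g}, {RR_MAX_MS:g})"))
            continue
        values.append(v)
    if bad:
        msg = "; ".join(f"line {n}: {m}" for n, m in bad[:10])
        if strict:
            raise ValueError(f"{path}: {len(bad)} rejected row(s): {msg}")
        warnings.warn(f"{path}: skipped {len(bad)} row(s): {msg}", stacklevel=2)
    if len(values) < 2:
        raise ValueError(f"{path}: fewer than 2 valid RR intervals")
    rr = RRSeries(intervals_ms=np.asarray(values),
                  meta={"subject": path.stem.removeprefix("rr_"),
                        "source": str(path)})
    rr.validate_physiological()
    return rr


def read_bp_csv(path: str | Path) -> list[BPSession]:
    """Read per-subject BP sessions from a ``subject,t_min,sbp,dbp`` CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BP file not found: {path}")
    df = pd.read_csv(path)
    required = {"subject", "t_min", "sbp", "dbp"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: BP CSV needs columns {sorted(required)}")
    bad = df[(df.sbp <= SBP_MIN) | (df.sbp >= SBP_MAX)]
    if not bad.empty:
        rows = (bad.index + 2).tolist()[:10]  # +2: header + 1-based
        raise ValueError(f"{path}: SBP outside ({SBP_MIN:g}, {SBP_MAX:g}) "
                         f"mmHg at csv row(s) {rows}")
    sessions = []
    for subject, grp in df.groupby("subject", sort=True):
        grp = grp.sort_values("t_min")
        if len(grp) < 8:
            warnings.warn(
                f"subject {subject}: only {len(grp)} BP readings "
                "(session shorter than 4 h assumed)", stacklevel=2,
            )
        if len(grp) < 2:
            raise ValueError(f"subject {subject}: fewer than 2 BP readings")
        sessions.append(BPSession(
            subject=str(subject),
            t_min=grp.t_min.to_numpy(float),
            sbp_mmhg=grp.sbp.to_numpy(float),
            dbp_mmhg=grp.dbp.to_numpy(float),
        ))
    return sessions


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    """Read the covariate table, indexed by subject."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"covariates file not found: {path}")
    df = pd.read_csv(path)
    required = {"subject", "filtered_volume_ml", "urea_mg_dl"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: covariates CSV needs columns "
                         f"{sorted(required)}")
    return df.set_index("subject")
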