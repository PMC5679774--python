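"""Reading, validation and grid preprocessing of thermogram tables.

The on-disk interchange format is a long CSV with one row per
(subject, temperature) and columns ``subject.ID``, ``status`` (case/control),
``temperature`` (°C) and ``DSC`` (excess specific heat capacity).  An optional
second CSV carries per-subject categorical covariates (``sex``, ``race``,
``yob_cat``, ``ra_oa_flag``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import RangeError, SchemaError, ValidationError

#: Accepted spellings of the binary status labels (matched case-insensitively).
_CASE_LABELS = {"case", "cases", "lupus", "1"}
_CONTROL_LABELS = {"control", "controls", "normal", "0"}

#: Tolerance (°C) used when comparing temperatures for grid matching.
TEMP_TOL = 1e-6


@dataclass
class ThermogramSet:
    """A cohort of thermogram curves sampled on a shared temperature grid.

    Attributes
    ----------
    grid : ndarray, shape (T,)
        Strictly increasing temperatures (°C).  After :func:`preprocess` the
        grid is uniform to within 1e-9 °C.
    values : ndarray, shape (n_subjects, T)
        Excess specific heat capacity, one row per subject.
    subject_ids : ndarray of str
        Unique subject identifiers, aligned with ``values`` rows.
    status : ndarray of int
        1 = case (lupus), 0 = control.
    covariates : pandas.DataFrame or None
        Optional per-subject categorical covariates indexed like
        ``subject_ids`` (columns among sex, race, yob_cat, ra_oa_flag).
    """

    grid: np.ndarray
    values: np.ndarray
    subject_ids: np.ndarray
    status: np.ndarray
    covariates: pd.DataFrame | None = None
    #: per-subject raw temperature/value arrays kept only when subjects were
    #: read with non-matching grids and still await interpolation
    _raw: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.status = np.asarray(self.status, dtype=int)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D (subjects x temperatures) array")
        n, T = self.values.shape
        if len(self.subject_ids) != n or len(self.status) != n:
            raise ValidationError("subject_ids/status length must match number of curves")
        if len(np.unique(self.subject_ids)) != n:
            raise ValidationError("subject_ids must be unique")
        if not np.all(np.isin(self.status, [0, 1])):
            raise ValidationError("status must be binary 0/1")
        if self._raw is None:
            if len(self.grid) != T:
                raise ValidationError("grid length must match number of value columns")
            if T > 1 and not np.all(np.diff(self.grid) > 0):
                raise ValidationError("grid must be strictly increasing")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_temps(self) -> int:
        return len(self.grid)

    @property
    def case_mask(self) -> np.ndarray:
        return self.status == 1

    def subset(self, mask: np.ndarray) -> "ThermogramSet":
        """Return the sub-cohort selected by a boolean or index mask."""
        ids = self.subject_ids[mask]
        cov = None
        if self.covariates is not None:
            cov = self.covariates.loc[ids]
        return ThermogramSet(self.grid.copy(), self.values[mask], ids,
                             self.status[mask], cov)

    def raoa_mask(self) -> np.ndarray:
        """Boolean mask of RA/OA-flagged, lupus-negative (control) subjects."""
        if self.covariates is None or "ra_oa_flag" not in self.covariates.columns:
            return np.zeros(self.n_subjects, dtype=bool)
        flags = self.covariates.loc[self.subject_ids, "ra_oa_flag"].to_numpy()
        flags = np.asarray([_truthy(v) for v in flags])
        return flags & (self.status == 0)


def _truthy(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"1", "true", "yes", "y"}
    return bool(v)


def _map_status(raw) -> int:
    s = str(raw).strip().lower()
    if s in _CASE_LABELS:
        return 1
    if s in _CONTROL_LABELS:
        return 0
    raise ValidationError(f"unrecognized status label {raw!r} (expected case/control)")


def read_long_csv(path, covariates_path=None) -> ThermogramSet:
    """Read a long-format thermogram CSV into a :class:`ThermogramSet`.

    Required columns: ``subject.ID``, ``status``, ``temperature``, ``DSC``.
    Each subject's rows are sorted by temperature.  Subjects whose observed
    temperatures differ from the majority grid are retained; run
    :func:`preprocess` to interpolate everyone onto a common uniform grid.
    """
    df = pd.read_csv(path)
    required = ["subject.ID", "status", "temperature", "DSC"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df[["subject.ID", "temperature"]].duplicated().any():
        dups = df.loc[df[["subject.ID", "temperature"]].duplicated(), "subject.ID"]
        raise ValidationError(
            f"duplicate (subject, temperature) rows for subject(s): "
            f"{sorted(set(dups.astype(str)))[:5]}")

    ids, temps, vals, status = [], [], [], []
    for sid, sub in df.groupby("subject.ID", sort=False):
        sub = sub.sort_values("temperature")
        st = set(sub["status"].map(_map_status))
        if len(st) != 1:
            raise ValidationError(f"inconsistent status labels for subject {sid!r}")
        ids.append(str(sid))
        status.append(st.pop())
        temps.append(sub["temperature"].to_numpy(dtype=float))
        vals.append(sub["DSC"].to_numpy(dtype=float))

    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path)
        if "subject.ID" not in cov.columns:
            raise SchemaError("covariates file missing required column: subject.ID")
        cov = cov.assign(**{"subject.ID": cov["subject.ID"].astype(str)})
        cov = cov.set_index("subject.ID")

    # common-grid fast path: all subjects observed at identical temperatures
    same = all(len(t) == len(temps[0]) and np.allclose(t, temps[0], atol=TEMP_TOL)
               for t in temps)
    if same:
        return ThermogramSet(temps[0], np.vstack(vals), np.array(ids),
                             np.array(status), cov)
    # ragged cohort: keep raw series; grid/values filled by preprocess()
    raw = list(zip(temps, vals))
    dummy = np.full((len(ids), 1), np.nan)
    return ThermogramSet(np.array([np.nan]), dummy, np.array(ids),
                         np.array(status), cov, _raw=raw)


def preprocess(ts: ThermogramSet, lo: float, hi: float, step: float,
               exclude_ids=()) -> ThermogramSet:
    """Exclude flagged subjects, truncate to [lo, hi] °C and interpolate.

    Every retained curve is linearly interpolated onto the closed uniform grid
    ``lo, lo+step, ..., hi`` (length ``round((hi-lo)/step) + 1``).  Subjects
    whose observed temperature range does not cover ``[lo, hi]`` raise a
    :class:`RangeError`; no silent extrapolation is performed.
    """
    if not lo < hi:
        raise RangeError(f"lo must be < hi (got {lo}, {hi})")
    if step <= 0:
        raise RangeError(f"step must be positive (got {step})")
    n_out = int(round((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n_out)

    exclude = {str(x) for x in exclude_ids}
    keep = [i for i, sid in enumerate(ts.subject_ids) if str(sid) not in exclude]
    if not keep:
        raise ValidationError("no subjects remain after exclusions")

    if ts._raw is not None:
        series = [ts._raw[i] for i in keep]
    else:
        series = [(ts.grid, ts.values[i]) for i in keep]

    bad = [str(ts.subject_ids[i]) for i, (t, _) in zip(keep, series)
           if t[0] > lo + TEMP_TOL or t[-1] < hi - TEMP_TOL]
    if bad:
        raise RangeError(
            f"observed temperature range does not cover [{lo}, {hi}] °C for "
            f"subject(s): {bad}")

    out = np.empty((len(keep), n_out))
    for row, (t, v) in enumerate(series):
        out[row] = np.interp(grid, t, v)

    ids = ts.subject_ids[keep]
    cov = ts.covariates.loc[ids] if ts.covariates is not None else None
    return ThermogramSet(grid, out, ids, ts.status[keep], cov)


def restrict_window(ts: ThermogramSet, lo: float, hi: float) -> ThermogramSet:
    """Drop grid columns outside the closed temperature window [lo, hi] °C."""
    mask = (ts.grid >= lo - TEMP_TOL) & (ts.grid <= hi + TEMP_TOL)
    if not mask.any():
        raise RangeError(
            f"window [{lo}, {hi}] °C does not intersect the grid "
            f"[{ts.grid[0]}, {ts.grid[-1]}] °C")
    return replace(ts, grid=ts.grid[mask], values=ts.values[:, mask])
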