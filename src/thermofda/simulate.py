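"""Synthetic thermogram cohorts for testing the analysis chain end to end.

The generator emulates the statistical structure of a matched case/control
DSC study: ~300 cases and ~300 controls on a 45-90 °C grid at 0.1 °C steps,
controls with the characteristic bimodal plasma thermogram (two denaturation
peaks), cases more unimodal with the group contrast concentrated in roughly
[60, 69] and [72, 85] °C, smooth within-subject noise, matched categorical
covariates, and a small RA/OA-positive, lupus-negative control subgroup.

Model
-----
Each group template is a sum of Gaussian peaks.  The case template is the
control template plus ``effect_size`` times a fixed contrast that transfers
amplitude out of the low-temperature peak region into the 72-85 °C shoulder
and shifts the curve slightly rightward, reproducing the qualitative
"bimodal controls vs. more unimodal cases" pattern.  Disease expression is
heterogeneous: each case draws its own contrast multiplier
``effect_size * N(1, effect_het)``, so mild cases overlap the control
distribution, as real autoimmune cohorts do.  Per-subject variation further
perturbs peak amplitudes and centers; residual noise is a smooth random
curve built from Gaussian coefficients on a coarse B-spline basis (knot
spacing = ``noise_smoothness``), not white noise on the grid, so that
saturated-basis FPCA is not dominated by grid-level jitter.

Amplitudes are in arbitrary normalized heat-capacity units; real thermogram
scales vary with normalization convention, so no physical unit is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import make_bspline_basis
from .errors import ConfigurationError, ValidationError
from .io import ThermogramSet

#: default documented seed for reproducible cohorts
DEFAULT_SEED = 20170919

#: control-group template peaks: (center °C, width °C, amplitude)
CONTROL_PEAKS = ((63.0, 2.2, 0.60), (70.5, 2.8, 0.52))

#: case-vs-control contrast at effect_size = 1: amplitude leaves the first
#: peak region and appears in the 72-85 °C shoulder
CONTRAST_PEAKS = ((63.5, 2.2, -0.10), (76.0, 3.5, +0.08))

#: rightward template shift of cases at effect_size = 1 (°C)
CASE_SHIFT = 0.4


@dataclass
class SimConfig:
    """Parameters of a synthetic thermogram cohort.

    Attributes
    ----------
    n_cases, n_controls : int
        Group sizes (defaults mirror a 300/300 matched design).
    n_raoa_controls : int
        Controls additionally flagged RA/OA-positive (drawn from the control
        distribution; lupus-negative).
    grid_lo, grid_hi, grid_step : float
        Temperature grid in °C (default 45-90 at 0.1, i.e. 451 points).
    peak_params : tuple
        Control-template Gaussian peaks as (center, width, amplitude).
    effect_size : float
        Scale of the case-vs-control contrast; 0 makes the two group
        distributions identical.
    effect_het : float
        Relative SD of the per-case contrast multiplier (disease-expression
        heterogeneity); 0 gives every case the full template contrast.
    subject_sd : float
        SD of per-subject perturbations: multiplicative on peak amplitudes
        (dimensionless) and, scaled by 2, additive on peak centers (°C).
    noise_sd : float
        SD of the smooth residual-noise basis coefficients (curve units).
    noise_smoothness : float
        Correlation length of the residual noise, as B-spline knot spacing
        in °C.
    covariate_frequencies : dict
        Category probabilities for sex, race and year-of-birth labels.
    raoa_shift : float
        Optional perturbation of the RA/OA subgroup template (default 0:
        RA/OA controls are ordinary controls).
    seed : int
        Master seed; all randomness flows from one generator.
    """

    n_cases: int = 300
    n_controls: int = 300
    n_raoa_controls: int = 17
    grid_lo: float = 45.0
    grid_hi: float = 90.0
    grid_step: float = 0.1
    peak_params: tuple = CONTROL_PEAKS
    effect_size: float = 1.0
    effect_het: float = 0.7
    subject_sd: float = 0.2
    noise_sd: float = 0.02
    noise_smoothness: float = 3.0
    covariate_frequencies: dict = field(default_factory=lambda: {
        "sex": {"F": 0.9, "M": 0.1},
        "race": {"Black": 0.5, "White": 0.5},
        "yob_cat": {"1924-1944": 0.25, "1945-1955": 0.25,
                    "1956-1971": 0.25, "1972-1993": 0.25},
    })
    raoa_shift: float = 0.0
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.grid_lo >= self.grid_hi:
            raise ConfigurationError("grid_lo must be < grid_hi")
        if self.grid_step <= 0:
            raise ConfigurationError("grid_step must be positive")
        for name in ("n_cases", "n_controls", "n_raoa_controls"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_raoa_controls > self.n_controls:
            raise ConfigurationError("n_raoa_controls must be <= n_controls")
        for name in ("subject_sd", "noise_sd", "effect_het"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.noise_smoothness <= 0:
            raise ConfigurationError("noise_smoothness must be positive")
        for cov, freq in self.covariate_frequencies.items():
            tot = sum(freq.values())
            if not np.isclose(tot, 1.0):
                raise ConfigurationError(
                    f"covariate_frequencies[{cov!r}] must sum to 1 (got {tot})")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)


def _gauss(t, center, width, amp):
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def control_template(config: SimConfig, t=None) -> np.ndarray:
    """Noise-free control mean curve on the grid."""
    t = config.grid if t is None else np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for c, w, a in config.peak_params:
        out += _gauss(t, c, w, a)
    return out


def case_template(config: SimConfig, t=None) -> np.ndarray:
    """Noise-free case mean curve: shifted control template + contrast."""
    t = config.grid if t is None else np.asarray(t, dtype=float)
    shifted = np.zeros_like(t)
    for c, w, a in config.peak_params:
        shifted += _gauss(t, c + CASE_SHIFT * config.effect_size, w, a)
    for c, w, a in CONTRAST_PEAKS:
        shifted += _gauss(t, c, w, a * config.effect_size)
    return shifted


def _subject_curve(config, t, is_case, rng):
    """One subject's noiseless curve: template with perturbed peaks.

    A case draws its own contrast multiplier e_i = effect_size * N(1,
    effect_het); controls draw the same random number (for stream parity)
    but apply no contrast, so effect_size = 0 makes the groups identical in
    distribution.
    """
    e_i = config.effect_size * (1.0 + config.effect_het * rng.standard_normal())
    if not is_case:
        e_i = 0.0
    out = np.zeros_like(t)
    for c, w, a in config.peak_params:
        amp = a * (1.0 + config.subject_sd * rng.standard_normal())
        cen = c + CASE_SHIFT * e_i + 2.0 * config.subject_sd * rng.standard_normal()
        out += _gauss(t, cen, w, amp)
    for c, w, a in CONTRAST_PEAKS:
        out += _gauss(t, c, w, a * e_i)
    return out


def _smooth_noise(config, t, rng, n_curves):
    """Smooth residual noise: Gaussian coefs on a coarse B-spline basis."""
    if config.noise_sd == 0:
        return np.zeros((n_curves, len(t)))
    span = config.grid_hi - config.grid_lo
    n_basis = max(4, int(np.ceil(span / config.noise_smoothness)) + 3)
    basis = make_bspline_basis((config.grid_lo, config.grid_hi), n_basis)
    Phi = basis.evaluate(t)
    coefs = config.noise_sd * rng.standard_normal((n_curves, n_basis))
    return coefs @ Phi.T


def _draw_covariates(config, n, rng):
    cols = {}
    for cov, freq in config.covariate_frequencies.items():
        levels = list(freq)
        probs = np.array([freq[k] for k in levels], dtype=float)
        cols[cov] = rng.choice(levels, size=n, p=probs)
    return cols


def generate_cohort(config: SimConfig | None = None, **overrides) -> ThermogramSet:
    """Generate a synthetic case/control thermogram cohort.

    Fully reproducible from ``config.seed``; keyword overrides are applied
    on top of the (default) config.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        raise ConfigurationError("pass either a SimConfig or keyword overrides")
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = config.grid
    n = config.n_cases + config.n_controls
    status = np.r_[np.ones(config.n_cases, dtype=int),
                   np.zeros(config.n_controls, dtype=int)]

    values = np.empty((n, len(t)))
    for i in range(n):
        values[i] = _subject_curve(config, t, status[i] == 1, rng)
    values += _smooth_noise(config, t, rng, n)

    ids = np.array([f"S{i + 1:04d}" for i in range(n)])
    cov = pd.DataFrame(_draw_covariates(config, n, rng), index=ids)
    cov.index.name = "subject.ID"
    # RA/OA flags: a random subset of controls, drawn from the control
    # distribution (optionally shifted by raoa_shift, default off)
    flag = np.zeros(n, dtype=int)
    ctrl_idx = np.flatnonzero(status == 0)
    if config.n_raoa_controls:
        chosen = rng.choice(ctrl_idx, size=config.n_raoa_controls, replace=False)
        flag[chosen] = 1
        if config.raoa_shift:
            values[chosen] += config.raoa_shift
    cov["ra_oa_flag"] = flag

    return ThermogramSet(grid=t, values=values, subject_ids=ids,
                         status=status, covariates=cov)


def write_long_csv(ts: ThermogramSet, path, covariates_path=None) -> None:
    """Write a cohort as the long interchange CSV (one row per subject/temp).

    Columns, in order: ``subject.ID``, ``status`` (case|control),
    ``temperature``, ``DSC``.  With ``covariates_path`` the per-subject
    covariate table is written alongside.  Raises on an empty cohort before
    touching the filesystem.
    """
    if ts.n_subjects == 0 or ts.n_temps == 0:
        raise ValidationError("refusing to write an empty thermogram set")
    n, T = ts.values.shape
    df = pd.DataFrame({
        "subject.ID": np.repeat(ts.subject_ids, T),
        "status": np.repeat(np.where(ts.status == 1, "case", "control"), T),
        "temperature": np.tile(ts.grid, n),
        "DSC": ts.values.ravel(),
    })
    df.to_csv(path, index=False)
    if covariates_path is not None and ts.covariates is not None:
        ts.covariates.loc[ts.subject_ids].to_csv(covariates_path)
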