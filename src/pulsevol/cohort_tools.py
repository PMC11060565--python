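"""Waveform I/O, cuff calibration, synthetic cohorts and comparison statistics.

No raw tonometry recordings ship with the package; the synthetic-subject
generator stands in for them.  It forward-simulates the radial beat of a
subject with known parameters, applies multiplicative measurement noise
(tonometry noise scales with signal), and attaches the ground truth so that
calibration accuracy can be scored.  Cohort parameters are drawn from the
group-level distributions estimated in hemodialysis patients and healthy
controls (truncated normals within the calibration bounds).

Comparison statistics follow agreement-analysis practice for ratio-scale
data: Pearson correlation plus Bland-Altman limits on natural-log transformed
stroke volumes, reported as geometric-mean ratios after antilogging.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .arterial_tree import ArterialTree, toy_tree
from .calibration import ParameterVector, build_subject_model, apply_parameters, \
    default_bounds
from .pulse_wave_solver import FAST, SolverConfig
from .simulation import PressureWaveform, foot_align, run_to_periodic, \
    sample_waveform, stroke_volume

KPA_TO_MMHG = 7.50062

#: group-level means and SDs of the four estimated parameters
PARAMETER_STATS = {
    "control": {"E_max": (2.56, 1.06), "t_m": (0.56, 0.05),
                "S_R": (2.02, 0.75), "S_C": (11.89, 4.39)},
    "hd": {"E_max": (3.13, 1.27), "t_m": (0.57, 0.09),
           "S_R": (1.66, 0.71), "S_C": (10.18, 4.34)},
}

#: group-level anthropometrics: height mean/SD (cm)
HEIGHT_STATS = {"control": (171.2, 6.8), "hd": (167.9, 9.4)}

#: plausible brachial-cuff and heart-period ranges used for synthetic subjects
CUFF_STATS = {
    "control": {"SBP": (120.0, 10.0), "DBP": (75.0, 8.0), "T": (0.85, 0.08)},
    "hd": {"SBP": (135.0, 15.0), "DBP": (80.0, 10.0), "T": (0.80, 0.10)},
}


@dataclass(frozen=True)
class SubjectMeta:
    """Subject metadata; ``true_params`` is set for synthetic subjects only."""

    id: str
    height: float            # cm
    SBP: float               # mmHg
    DBP: float               # mmHg
    T: float                 # s
    group: str = "control"
    true_params: ParameterVector | None = None
    true_sv: float | None = None   # ml, synthetic subjects
    # pass-through device quality indices (never computed here)
    operator_index: float | None = None
    signal_quality: float | None = None

    def __post_init__(self) -> None:
        if not (self.SBP > self.DBP > 0):
            raise ValueError("need SBP > DBP > 0")
        if self.T <= 0 or self.height <= 0:
            raise ValueError("need positive height and heart period")


# ---------------------------------------------------------------------------
# waveform files
# ---------------------------------------------------------------------------

def write_waveform(w: PressureWaveform, path) -> None:
    """Write a beat as a two-column CSV with a unit header and period metadata."""
    lines = ["# pulsevol waveform", f"# period_s = {float(w.T)!r}"]
    if w.sbp is not None:
        lines.append(f"# sbp_mmhg = {float(w.sbp)!r}")
    if w.dbp is not None:
        lines.append(f"# dbp_mmhg = {float(w.dbp)!r}")
    lines.append("time_s,pressure_mmHg")
    for t, p in zip(w.t, w.p):
        lines.append(f"{float(t)!r},{float(p)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_waveform(path) -> PressureWaveform:
    """Load a beat from a two-column time/pressure table.

    The pressure column name must carry its unit (``pressure_mmHg`` or
    ``pressure_kPa``); kPa data are converted (1 kPa = 7.50062 mmHg).  The
    period is taken from a ``# period_s = ...`` comment when present,
    otherwise extrapolated from the sample spacing.  Rejects non-monotone
    time axes.
    """
    text = Path(path).read_text()
    meta = {}
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            key, _, val = line.lstrip("# ").partition("=")
            try:
                meta[key.strip().lower()] = float(val)
            except ValueError:
                pass
    df = pd.read_csv(io.StringIO(text), comment="#")
    cols = {c.lower(): c for c in df.columns}
    tcol = next((cols[c] for c in cols if c.startswith("time")), None)
    pcol = next((cols[c] for c in cols if c.startswith("pressure")), None)
    if tcol is None or pcol is None:
        raise ValueError("waveform file needs time_* and pressure_* columns")
    if pcol.lower().endswith("mmhg"):
        scale = 1.0
    elif pcol.lower().endswith("kpa"):
        scale = KPA_TO_MMHG
    else:
        raise ValueError(f"pressure column {pcol!r} lacks a unit suffix")
    t = df[tcol].to_numpy(float)
    p = df[pcol].to_numpy(float) * scale
    if np.any(np.diff(t) <= 0):
        raise ValueError("time samples must be strictly increasing")
    T = meta.get("period_s", float(t[-1] + np.median(np.diff(t)) - t[0]))
    return PressureWaveform(t=t, p=p, T=T,
                            sbp=meta.get("sbp_mmhg"), dbp=meta.get("dbp_mmhg"))


def calibrate_to_cuff(raw: PressureWaveform, SBP: float, DBP: float) -> PressureWaveform:
    """Affine rescaling of a raw beat so min -> DBP and max -> SBP (mmHg).

    This emulates the calibration of a tonometric recording against brachial
    cuff pressures; already-calibrated waveforms are fixed points.
    """
    if not SBP > DBP:
        raise ValueError("need SBP > DBP")
    lo, hi = float(np.min(raw.p)), float(np.max(raw.p))
    if hi - lo < 1e-12:
        raise ValueError("flat waveform cannot be calibrated")
    p = DBP + (raw.p - lo) * (SBP - DBP) / (hi - lo)
    return replace(raw, p=p, sbp=SBP, dbp=DBP)


# ---------------------------------------------------------------------------
# synthetic subjects
# ---------------------------------------------------------------------------

def generate_synthetic_subject(true_p: ParameterVector, meta: SubjectMeta,
                               noise_sd: float = 0.0, seed: int | None = None,
                               tree: ArterialTree | None = None,
                               solver: SolverConfig = FAST,
                               n_cycles: int = 9, drift_rel: float = 0.0):
    """Forward-simulate a subject's radial beat with known parameters.

    Multiplicative Gaussian noise of relative SD ``noise_sd`` is applied
    pointwise (``drift_rel`` adds an optional slow multiplicative baseline
    undulation of that relative amplitude, off by default), the beat is
    re-foot-aligned, and the cuff pressures in the returned metadata are made
    consistent with the (noise-free) simulated extremes.  Returns
    ``(waveform, meta with truth attached)``.
    """
    if tree is None:
        tree = toy_tree()
    model = build_subject_model(tree, meta, solver=solver)
    m = apply_parameters(model, true_p, default_bounds(meta.T))
    sol = run_to_periodic(m, max_cycles=n_cycles, tol_mmHg=0.0,
                          min_cycles=n_cycles)
    w = sample_waveform(sol)
    sv = stroke_volume(sol)
    p = w.p
    if noise_sd > 0 or drift_rel > 0:
        rng = np.random.default_rng(seed)
        if noise_sd > 0:
            p = p * (1.0 + noise_sd * rng.standard_normal(p.size))
        if drift_rel > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            p = p * (1.0 + drift_rel * np.sin(2.0 * np.pi * w.t / w.T + phase))
    w = foot_align(replace(w, p=p, sbp=float(np.max(w.p)), dbp=float(np.min(w.p))))
    meta = replace(meta, SBP=float(np.max(w.p)), DBP=float(np.min(w.p)),
                   true_params=true_p, true_sv=sv)
    return w, meta


def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def generate_cohort(n: int, group: str = "control",
                    seed: int | None = None) -> list[SubjectMeta]:
    """Draw ``n`` synthetic subjects from a group's parameter distributions.

    Parameters come from the group means/SDs (truncated to the calibration
    bounds by reject-and-resample); heights from the group anthropometrics;
    cuff pressures and heart period from configured plausible ranges.
    Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if group not in PARAMETER_STATS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    pstats, cuff = PARAMETER_STATS[group], CUFF_STATS[group]
    hmean, hsd = HEIGHT_STATS[group]
    out = []
    for i in range(n):
        T = _trunc_normal(rng, *cuff["T"], 0.6, 1.2)
        b = default_bounds(T)
        (e_lo, t_lo, r_lo, c_lo), (e_hi, t_hi, r_hi, c_hi) = b.lo, b.hi
        p = ParameterVector(
            E_max=_trunc_normal(rng, *pstats["E_max"], e_lo, e_hi),
            t_m=_trunc_normal(rng, *pstats["t_m"], t_lo, t_hi),
            S_R=_trunc_normal(rng, *pstats["S_R"], r_lo, r_hi),
            S_C=_trunc_normal(rng, *pstats["S_C"], c_lo, c_hi))
        dbp = _trunc_normal(rng, *cuff["DBP"], 50.0, 110.0)
        sbp = max(_trunc_normal(rng, *cuff["SBP"], 90.0, 200.0), dbp + 20.0)
        out.append(SubjectMeta(
            id=f"{group}-{i:03d}",
            height=_trunc_normal(rng, hmean, hsd, 140.0, 210.0),
            SBP=sbp, DBP=dbp, T=T, group=group, true_params=p))
    return out


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Log-scale agreement between two SV estimators.

    Differences are natural logs (model minus reference); limits of agreement
    are mean +/- 1.96 SD.  Antilogged values are geometric-mean ratios: a
    ratio of 0.66 means the model reads on average 34% lower.
    """

    mean_log_diff: float
    sd_log_diff: float
    loa_lower: float
    loa_upper: float
    ratio: float
    ratio_lower: float
    ratio_upper: float

    @property
    def mean_percent_difference(self) -> float:
        """Average percent deviation of the model from the reference."""
        return (self.ratio - 1.0) * 100.0


def bland_altman_log(model_sv, ref_sv) -> BlandAltmanResult:
    """Bland-Altman agreement on natural-log transformed paired stroke volumes."""
    m = np.asarray(model_sv, float)
    r = np.asarray(ref_sv, float)
    if m.shape != r.shape or m.size < 2:
        raise ValueError("need >= 2 paired values")
    if np.any(m <= 0) or np.any(r <= 0):
        raise ValueError("stroke volumes must be positive")
    d = np.log(m) - np.log(r)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    return BlandAltmanResult(mean_log_diff=mean, sd_log_diff=sd,
                             loa_lower=lo, loa_upper=hi,
                             ratio=math.exp(mean), ratio_lower=math.exp(lo),
                             ratio_upper=math.exp(hi))
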