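"""Block-design fNIRS "battery of tests" for the warble paradigm.

Five converging analyses establish whether a slow, task-locked
hemodynamic response is present and spatially specific:

1. block-averaged epochs (percent change from a pre-stimulus baseline)
   with the standard error of the mean;
2. PCA on the epoch matrix — a consistent response surfaces as PC1;
3. a GLM with a task regressor (2-s boxcars convolved with a
   negative-going gamma kernel troughing ~12 s post-onset), per-subject
   OLS betas taken to a one-sample group t-test per channel with
   Benjamini–Hochberg FDR correction;
4. time-locked cross-correlation between signal and regressor;
5. stimulation-vs-silence contrasts on Δ[HbT] (segment correlations and
   t-tests) and a repeated-measures ANOVA on the GLM betas with
   "channel" as the within-subject factor, Holm-corrected post-hoc
   paired t-tests — a localized response differs across channels,
   whereas a global systemic artifact does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stimuli import StimulusProtocol
from .synthetic import Modality, TimeSeriesRecording, gamma_response_kernel

__all__ = [
    "PcaResult",
    "GlmFit",
    "SpatialAnovaResult",
    "ContrastMatrices",
    "BlockEpochs",
    "total_hemoglobin",
    "smooth",
    "epoch_blocks",
    "grand_average",
    "pca_epochs",
    "task_regressor",
    "glm_single",
    "glm_task",
    "crosscorr_channels",
    "crosscorr_task",
    "compare_segments",
    "stim_silence_contrast",
    "spatial_anova",
    "holm_correct",
    "fdr_correct",
    "fractional_change",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def total_hemoglobin(hbo: np.ndarray, hbr: np.ndarray) -> np.ndarray:
    """Total hemoglobin change: Δ[HbT] = Δ[HbO] + Δ[HbR], elementwise."""
    hbo, hbr = np.asarray(hbo), np.asarray(hbr)
    if hbo.shape != hbr.shape:
        raise ValueError("HbO and HbR must have equal shapes")
    return hbo + hbr


def smooth(series: np.ndarray, sample_rate: float, window_s: float = 0.2) -> np.ndarray:
    """Centered moving average along the last axis; edges are handled by
    truncating the window, so the length (and a constant input) are
    preserved exactly."""
    x = np.asarray(series, dtype=float)
    w = max(1, int(round(window_s * sample_rate)))
    if w == 1:
        return x.copy()
    kernel = np.ones(w)
    counts = np.convolve(np.ones(x.shape[-1]), kernel, mode="same")
    out = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same") / counts, -1, x
    )
    return out


def fractional_change(data: np.ndarray) -> np.ndarray:
    """Per-channel fractional change around the channel mean: x/mean − 1.

    Puts raw light intensity on the dimensionless scale the battery
    statistics operate on (a 2% dip becomes −0.02)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    ref = data.mean(axis=-1, keepdims=True)
    if np.any(np.abs(ref) < 1e-300):
        raise ValueError("channel mean is zero; cannot form fractional change")
    return data / ref - 1.0


# ---------------------------------------------------------------------------
# block epochs / grand average / PCA
# ---------------------------------------------------------------------------

@dataclass
class BlockEpochs:
    """Percent-change epochs around task onsets.

    ``percent`` is channels x epochs x time; ``times`` is seconds
    relative to onset.
    """

    percent: np.ndarray
    times: np.ndarray
    sample_rate: float
    n_dropped: int = 0


def epoch_blocks(
    series: np.ndarray,
    sample_rate: float,
    onsets: np.ndarray,
    window: tuple[float, float] = (-5.0, 15.0),
    baseline: tuple[float, float] = (-5.0, 0.0),
) -> BlockEpochs:
    """Cut per-onset epochs expressed as percent change from baseline:
    ``100 * (x - mean(baseline)) / |mean(baseline)|`` per channel and
    epoch, the reference being the pre-stimulus mean of the raw trace.
    Epochs escaping the recording are dropped (and counted)."""
    data = np.atleast_2d(np.asarray(series, dtype=float))
    n = data.shape[-1]
    i0, i1 = (int(round(w * sample_rate)) for w in window)
    b0, b1 = (int(round(b * sample_rate)) for b in baseline)
    rel = np.arange(i0, i1)
    epochs, n_dropped = [], 0
    for onset in np.atleast_1d(onsets):
        c = int(round(onset * sample_rate))
        if c + i0 < 0 or c + i1 > n or c + b0 < 0:
            n_dropped += 1
            continue
        seg = data[:, c + rel]
        ref = data[:, c + b0 : c + b1].mean(axis=-1, keepdims=True)
        if np.any(np.abs(ref) < 1e-300):
            raise ValueError("baseline reference is zero")
        epochs.append(100.0 * (seg - ref) / np.abs(ref))
    if epochs:
        percent = np.stack(epochs, axis=1)
    else:
        percent = np.empty((data.shape[0], 0, rel.size))
    return BlockEpochs(percent, rel / sample_rate, sample_rate, n_dropped)


def grand_average(epochs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard error (sd/sqrt(n)) over the first axis."""
    epochs = np.asarray(epochs, dtype=float)
    if epochs.shape[0] < 2:
        raise ValueError("grand average needs at least 2 epochs")
    mean = epochs.mean(axis=0)
    sem = epochs.std(axis=0, ddof=1) / np.sqrt(epochs.shape[0])
    return mean, sem


@dataclass
class PcaResult:
    components: np.ndarray  # n_components x time
    explained_variance_fraction: np.ndarray


def pca_epochs(epochs: np.ndarray, n_components: int | None = None) -> PcaResult:
    """Principal temporal patterns of an epochs x time matrix.

    Uses the singular-value decomposition of the epoch matrix itself
    (no per-time-point re-centering): a response that recurs across
    epochs then dominates the first component, so PC1 tracks the
    averaged evoked shape rather than only its epoch-to-epoch
    deviations.  Components are orthonormal; the explained fractions
    are the squared singular values normalized to sum to 1."""
    X = np.asarray(epochs, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 epochs")
    k = min(n_components or min(X.shape), min(X.shape))
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    energy = s**2
    total = energy.sum()
    fractions = energy / total if total > 0 else energy
    return PcaResult(vt[:k], fractions[:k])


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def task_regressor(
    n_samples: int,
    sample_rate: float,
    protocol: StimulusProtocol,
    trough_latency: float = 12.0,
    response_duration: float = 30.0,
) -> np.ndarray:
    """Task regressor: 2-s boxcars at each warble onset convolved with a
    negative-going gamma kernel (trough ``trough_latency`` s after
    onset), normalized so the deepest trough is −1.  A channel beta then
    estimates the fractional (or percent) dip amplitude directly."""
    box = np.zeros(n_samples)
    for e in protocol.events:
        if e.kind == "silence":
            continue
        a = int(round(e.onset * sample_rate))
        b = min(n_samples, int(round((e.onset + e.duration) * sample_rate)))
        box[a:b] = 1.0
    kernel = gamma_response_kernel(trough_latency, response_duration, sample_rate)
    reg = np.convolve(box, -kernel)[:n_samples]
    peak = np.abs(reg).max() if reg.size else 0.0
    if peak == 0:
        raise ValueError("protocol has no task events inside the recording")
    return reg / peak


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each row of y on design X: betas, t and two-sided p for the
    last design column."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    pinv = np.linalg.pinv(X)
    coef = y @ pinv.T  # channels x p
    resid = y - coef @ X.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=-1) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    beta = coef[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p_val = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, t, p_val


def glm_single(
    series: np.ndarray,
    sample_rate: float,
    protocol: StimulusProtocol,
    trough_latency: float = 12.0,
    response_duration: float = 30.0,
) -> pd.DataFrame:
    """Per-channel OLS of one recording on [intercept, linear drift,
    task regressor]; returns beta, t and p for the task column."""
    data = np.atleast_2d(np.asarray(series, dtype=float))
    n = data.shape[-1]
    reg = task_regressor(n, sample_rate, protocol, trough_latency, response_duration)
    t_c = np.arange(n) / sample_rate
    X = np.column_stack([np.ones(n), t_c - t_c.mean(), reg])
    beta, t, p = _ols(data, X)
    return pd.DataFrame({"channel": np.arange(1, data.shape[0] + 1),
                         "beta": beta, "t_statistic": t, "p_value": p})


@dataclass
class GlmFit:
    """Group-level GLM result in the shape of the per-channel report
    table: one-sample t over subject betas, FDR-corrected."""

    table: pd.DataFrame
    subject_betas: np.ndarray  # subjects x channels
    alpha: float = ALPHA


def glm_task(
    recordings: list[TimeSeriesRecording] | list[np.ndarray],
    protocol: StimulusProtocol,
    sample_rate: float | None = None,
    trough_latency: float = 12.0,
    response_duration: float = 30.0,
    alpha: float = ALPHA,
) -> GlmFit:
    """Fit the task GLM per subject on fractional-change raw intensity and
    combine with a one-sample t-test across subjects per channel,
    FDR-corrected (Benjamini–Hochberg) over channels."""
    betas = []
    for rec in recordings:
        if isinstance(rec, TimeSeriesRecording):
            fs = rec.sample_rate
            data = fractional_change(rec.data) if rec.modality is Modality.FNIRS_RAW else rec.data
        else:
            if sample_rate is None:
                raise ValueError("sample_rate required for bare arrays")
            fs = sample_rate
            data = np.atleast_2d(np.asarray(rec, dtype=float))
        fit = glm_single(data, fs, protocol, trough_latency, response_duration)
        betas.append(fit["beta"].to_numpy())
    B = np.vstack(betas)  # subjects x channels
    t, p = stats.ttest_1samp(B, 0.0, axis=0)
    p_fdr = fdr_correct(p)
    table = pd.DataFrame(
        {
            "channel": [f"Ch {i + 1}" for i in range(B.shape[1])],
            "t_statistic": t,
            "p_value": p,
            "mean_beta": B.mean(axis=0),
            "p_fdr": p_fdr,
            "significant": p_fdr < alpha,
        }
    )
    return GlmFit(table, B, alpha)


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

def crosscorr_channels(
    series: np.ndarray,
    regressor: np.ndarray,
    sample_rate: float,
    max_lag_s: float = 5.0,
) -> pd.DataFrame:
    """Per-channel peak lagged similarity with the task regressor.

    Reports both the normalized correlation coefficient (``peak_r``) and
    the unnormalized cross-covariance (``peak_cov``, sample units), each
    with its lag; the signed peak is the value of largest magnitude with
    its sign preserved, so task-locked intensity decreases against a
    positive-going regressor come out negative."""
    data = np.atleast_2d(np.asarray(series, dtype=float))
    reg = np.asarray(regressor, dtype=float)
    if data.shape[-1] != reg.size:
        raise ValueError("series and regressor must share the time grid")
    max_k = int(round(max_lag_s * sample_rate))
    rows = []
    rc = reg - reg.mean()
    for ch in range(data.shape[0]):
        xc = data[ch] - data[ch].mean()
        best_r, best_r_lag, best_c, best_c_lag = 0.0, 0.0, 0.0, 0.0
        for k in range(-max_k, max_k + 1):
            if k >= 0:
                x, y = xc[k:], rc[: rc.size - k]
            else:
                x, y = xc[: xc.size + k], rc[-k:]
            if x.size < 3:
                continue
            cov = float((x * y).sum())
            sx, sy = x.std(), y.std()
            r = 0.0 if sx == 0 or sy == 0 else float(
                ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
            )
            if abs(r) > abs(best_r):
                best_r, best_r_lag = r, k / sample_rate
            if abs(cov) > abs(best_c):
                best_c, best_c_lag = cov, k / sample_rate
        rows.append((ch + 1, best_r, best_r_lag, best_c, best_c_lag))
    return pd.DataFrame(
        rows, columns=["channel", "peak_r", "lag_r_s", "peak_cov", "lag_cov_s"]
    )


def crosscorr_task(
    recordings: list[TimeSeriesRecording] | list[np.ndarray],
    protocol: StimulusProtocol,
    sample_rate: float | None = None,
    max_lag_s: float = 5.0,
    trough_latency: float = 12.0,
    response_duration: float = 30.0,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Group cross-correlation table: per-subject peak values against a
    positive-going task regressor (so a task-locked intensity decrease
    yields negative peaks), then a one-sample t across subjects per
    channel with FDR correction.  ``mean_peak_cov`` carries the
    unnormalized cross-covariance magnitudes alongside the normalized
    ``mean_peak_r``."""
    peak_r, peak_cov = [], []
    for rec in recordings:
        if isinstance(rec, TimeSeriesRecording):
            fs = rec.sample_rate
            data = fractional_change(rec.data) if rec.modality is Modality.FNIRS_RAW else rec.data
        else:
            if sample_rate is None:
                raise ValueError("sample_rate required for bare arrays")
            fs = sample_rate
            data = np.atleast_2d(np.asarray(rec, dtype=float))
        reg = -task_regressor(data.shape[-1], fs, protocol, trough_latency, response_duration)
        df = crosscorr_channels(data, reg, fs, max_lag_s)
        peak_r.append(df["peak_r"].to_numpy())
        peak_cov.append(df["peak_cov"].to_numpy())
    R = np.vstack(peak_r)
    C = np.vstack(peak_cov)
    t, p = stats.ttest_1samp(R, 0.0, axis=0)
    p_fdr = fdr_correct(p)
    return pd.DataFrame(
        {
            "channel": [f"Ch {i + 1}" for i in range(R.shape[1])],
            "t_statistic": t,
            "p_value": p,
            "mean_peak_r": R.mean(axis=0),
            "mean_peak_cov": C.mean(axis=0),
            "p_fdr": p_fdr,
            "significant": p_fdr < alpha,
        }
    )


# ---------------------------------------------------------------------------
# stimulation vs silence
# ---------------------------------------------------------------------------

def compare_segments(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson r between two equal-length segments and the two-sample
    t-test p-value on their samples.  Degenerate (constant) segments get
    r = 0 unless identical, in which case r = 1."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("segments must have equal length")
    if a.std() == 0 or b.std() == 0:
        r = 1.0 if np.array_equal(a, b) else 0.0
    else:
        r = float(stats.pearsonr(a, b).statistic)
    t_res = stats.ttest_ind(a, b)
    p = float(t_res.pvalue)
    if np.isnan(p):  # identical constant segments
        p = 1.0
    return r, p


@dataclass
class ContrastMatrices:
    """Stimulation-vs-silence contrast: (n_stim x n_silence) matrices of
    mean Pearson r and mean t-test p, with threshold marks and the p
    histogram (0.005-wide bins, an edge exactly at 0.05)."""

    r_matrix: np.ndarray
    p_matrix: np.ndarray
    r_marks: np.ndarray = field(init=False)
    p_marks: np.ndarray = field(init=False)
    p_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    r_threshold: float = 0.25
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if self.r_matrix.shape != self.p_matrix.shape:
            raise ValueError("matrices must have the same shape")
        self.r_marks = np.abs(self.r_matrix) > self.r_threshold
        self.p_marks = self.p_matrix < self.alpha

    def p_histogram(self) -> tuple[np.ndarray, np.ndarray]:
        edges = np.arange(0.0, 1.0 + 0.005, 0.005)
        counts, _ = np.histogram(self.p_values, bins=edges)
        return counts, edges


def _segment_windows(
    protocol: StimulusProtocol, segment_length: float
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    stim, silence = [], []
    for e in protocol.events:
        if e.kind == "silence":
            continue
        stim.append((e.onset, e.onset + segment_length))
        silence.append((e.onset - segment_length, e.onset))
    return stim, silence


def stim_silence_contrast(
    recordings: list[TimeSeriesRecording] | list[tuple[np.ndarray, float]],
    protocol: StimulusProtocol,
    segment_length: float = 2.0,
    r_threshold: float = 0.25,
    alpha: float = ALPHA,
) -> ContrastMatrices:
    """Correlate/t-test every (stimulation segment, silence segment) pair
    of the Δ[HbT] time courses, per channel, and average the matrices
    over channels and subjects.  Silence segments are the
    ``segment_length`` windows immediately preceding each onset."""
    r_sum = p_sum = None
    count = 0
    all_p: list[float] = []
    for rec in recordings:
        if isinstance(rec, TimeSeriesRecording):
            _, _, hbt, _ = rec.chromophores()
            fs = rec.sample_rate
        else:
            hbt, fs = np.atleast_2d(np.asarray(rec[0], dtype=float)), rec[1]
        stim_w, sil_w = _segment_windows(protocol, segment_length)
        if not stim_w or not sil_w:
            raise ValueError("need at least one stimulation and one silence segment")
        n_seg = int(round(segment_length * fs))
        r_mat = np.zeros((len(stim_w), len(sil_w)))
        p_mat = np.zeros_like(r_mat)
        for ch in range(hbt.shape[0]):
            for i, (a0, _) in enumerate(stim_w):
                sa = hbt[ch, int(round(a0 * fs)) : int(round(a0 * fs)) + n_seg]
                for j, (b0, _) in enumerate(sil_w):
                    sb = hbt[ch, int(round(b0 * fs)) : int(round(b0 * fs)) + n_seg]
                    if sa.size != n_seg or sb.size != n_seg:
                        raise ValueError("segment escapes the recording")
                    r, p = compare_segments(sa, sb)
                    r_mat[i, j] += r
                    p_mat[i, j] += p
                    all_p.append(p)
        r_mat /= hbt.shape[0]
        p_mat /= hbt.shape[0]
        r_sum = r_mat if r_sum is None else r_sum + r_mat
        p_sum = p_mat if p_sum is None else p_sum + p_mat
        count += 1
    return ContrastMatrices(
        r_matrix=r_sum / count,
        p_matrix=p_sum / count,
        p_values=np.array(all_p),
        r_threshold=r_threshold,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# spatial specificity
# ---------------------------------------------------------------------------

@dataclass
class SpatialAnovaResult:
    F_value: float
    df_num: float
    df_den: float
    p_value: float
    posthoc: pd.DataFrame  # channel x channel Holm-corrected p matrix


def spatial_anova(
    betas: np.ndarray,
    alpha: float = ALPHA,
    sphericity_correction: bool = False,
) -> SpatialAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x channels beta
    matrix with channel as the within-subject factor, df = (C−1,
    (C−1)(S−1)); no sphericity correction by default (Greenhouse–Geisser
    optionally).  Post-hoc: all-pairs paired t-tests, Holm-corrected."""
    B = np.asarray(betas, dtype=float)
    if B.ndim != 2 or B.shape[0] < 2 or B.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 channels")
    if not np.all(np.isfinite(B)):
        raise ValueError("beta matrix must be complete")
    S, C = B.shape
    df1, df2 = C - 1, (C - 1) * (S - 1)

    # degenerate design: no between-channel variation -> F = 0, p = 1
    ss_channel = S * ((B.mean(axis=0) - B.mean()) ** 2).sum()
    if ss_channel <= 1e-24 * max(1.0, float((B**2).sum())):
        posthoc0 = pd.DataFrame(
            np.where(np.eye(C, dtype=bool), np.nan, 1.0),
            index=[f"Ch {i + 1}" for i in range(C)],
            columns=[f"Ch {i + 1}" for i in range(C)],
        )
        return SpatialAnovaResult(0.0, float(df1), float(df2), 1.0, posthoc0)

    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(S), C),
            "channel": np.tile(np.arange(C), S),
            "beta": B.ravel(),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="beta", within="channel", subject="subject",
        correction=sphericity_correction, detailed=False,
    )
    row = aov.iloc[0]

    def _col(*names: str) -> str | None:
        return next((n for n in names if n in aov.columns), None)

    gg = _col("p_GG_corr", "p-GG-corr")
    unc = _col("p_unc", "p-unc")
    if sphericity_correction and gg is not None and not np.isnan(row[gg]):
        p_value = float(row[gg])
    else:
        p_value = float(row[unc])

    pairs = [(i, j) for i in range(C) for j in range(i + 1, C)]
    p_raw = np.array([stats.ttest_rel(B[:, i], B[:, j]).pvalue for i, j in pairs])
    p_holm = holm_correct(p_raw)
    mat = np.full((C, C), np.nan)
    for (i, j), p in zip(pairs, p_holm):
        mat[i, j] = mat[j, i] = p
    posthoc = pd.DataFrame(
        mat,
        index=[f"Ch {i + 1}" for i in range(C)],
        columns=[f"Ch {i + 1}" for i in range(C)],
    )
    return SpatialAnovaResult(
        F_value=float(row["F"]),
        df_num=float(row["ddof1"]),
        df_den=float(row["ddof2"]),
        p_value=p_value,
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# multiple-testing corrections
# ---------------------------------------------------------------------------

def holm_correct(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def fdr_correct(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
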