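"""Organ dose extraction and the study's statistical comparisons.

Organ doses are voxel-mean absorbed doses over the organ masks (the masks
are single-material, so mass weighting would change nothing). Setups are
compared with the symmetric relative dose difference

    100 * (Dose_dev - Dose_ref) / ((Dose_dev + Dose_ref) / 2)

which is antisymmetric under swapping the two doses and bounded in
(-200, 200) %. Across-model comparisons use paired t-tests, one-way
repeated-measures ANOVA with Dunnett many-to-one post hoc correction
against the reference condition, and Bland-Altman agreement analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OrganDoseTable", "RelDiffTable", "BlandAltmanResult", "organ_dose",
    "relative_difference", "paired_t", "rm_anova_dunnett", "bland_altman",
]


class MissingOrganError(ValueError):
    pass


class IncompleteDesignError(ValueError):
    pass


@dataclass
class OrganDoseRow:
    model_id: str
    scanner: str
    setup_id: str
    organ: str
    mean_dose_mgy: float
    n_voxels: int
    se_mgy: float


class OrganDoseTable:
    """Collection of per-(model, scanner, setup, organ) mean doses."""

    def __init__(self, rows=None):
        self.rows: list[OrganDoseRow] = list(rows) if rows else []

    def append(self, row: OrganDoseRow):
        self.rows.append(row)

    def extend(self, rows):
        self.rows.extend(rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([r.__dict__ for r in self.rows])


class RelDiffTable:
    """Per-(model, scanner, setup, organ) relative dose differences in %."""

    def __init__(self):
        self.rows: list[dict] = []

    def append(self, model_id, scanner, setup_id, organ, dose_dev, dose_ref):
        self.rows.append(dict(
            model_id=model_id, scanner=scanner, setup_id=setup_id, organ=organ,
            dose_dev_mgy=dose_dev, dose_ref_mgy=dose_ref,
            rel_diff_pct=relative_difference(dose_dev, dose_ref)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def organ_dose(dosemap, phantom, scanner="", setup_id="", organs=None
               ) -> list[OrganDoseRow]:
    """Mean dose over each organ mask, with a propagated MC standard error.

    The standard error is the mask-internal voxel SD over sqrt(n voxels),
    which treats voxel tallies as approximately independent; it is a
    resolution-level proxy for the true MC uncertainty, adequate for
    weighting and reporting.
    """
    if dosemap.dose_mgy.shape != phantom.shape:
        raise ValueError("dose map and phantom grids are not aligned")
    if organs is None:
        organs = list(phantom.masks)
    rows = []
    for organ in organs:
        mask = phantom.masks.get(organ)
        if mask is None or not mask.any():
            if organ == "breasts" and phantom.sex == "male":
                continue
            raise MissingOrganError(f"empty mask for organ {organ!r}")
        vals = dosemap.dose_mgy[mask]
        rows.append(OrganDoseRow(
            model_id=phantom.model_id, scanner=scanner, setup_id=setup_id,
            organ=organ, mean_dose_mgy=float(vals.mean()),
            n_voxels=int(mask.sum()),
            se_mgy=float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1 else 0.0))
    return rows


def relative_difference(dose_dev: float, dose_ref: float) -> float:
    """Symmetric relative dose difference in percent."""
    if dose_dev + dose_ref <= 0:
        raise ZeroDivisionError(
            "relative difference undefined: non-positive dose pair")
    return float((dose_dev - dose_ref) / ((dose_dev + dose_ref) / 2.0) * 100.0)


def paired_t(x, y) -> tuple[float, int, float]:
    """Classical paired t-test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, n - 1, 1.0
        return float(np.inf * np.sign(d.mean())), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def _dunnett_adjusted_p(t_obs: np.ndarray, df: int, n_draws: int = 200_000,
                        seed: int = 97) -> np.ndarray:
    """Many-to-one max-|t| adjustment by seeded Monte Carlo.

    Contrasts of k conditions against a shared control have pairwise
    correlation 1/2 under equal variances; the null max-|t| distribution is
    multivariate t with that structure. Adjusted p is P(max_j |T_j| >=
    |t_obs|).
    """
    k = len(t_obs)
    rng = np.random.default_rng(seed)
    cov = np.full((k, k), 0.5)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_draws, k)) @ chol.T
    w = rng.chisquare(df, n_draws) / df
    max_abs_t = np.abs(z / np.sqrt(w)[:, None]).max(axis=1)
    return np.array([(np.sum(max_abs_t >= abs(t)) + 1) / (n_draws + 1)
                     for t in t_obs])


def rm_anova_dunnett(data: np.ndarray, condition_ids, control,
                     n_draws: int = 200_000, seed: int = 97) -> dict:
    """One-way repeated-measures ANOVA plus Dunnett many-to-one post hoc.

    Parameters
    ----------
    data : (n_subjects, n_conditions) complete matrix.
    condition_ids : labels of the columns.
    control : the label of the reference condition.

    Returns a dict with the ANOVA F and df, and per-condition paired t,
    unadjusted and Dunnett-adjusted p-values against the control.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3 or data.shape[1] < 2:
        raise IncompleteDesignError(
            "need a complete subjects x conditions matrix, >=3 subjects, "
            ">=2 conditions")
    if np.any(~np.isfinite(data)):
        raise IncompleteDesignError("missing cells in the design")
    condition_ids = list(condition_ids)
    if control not in condition_ids:
        raise ValueError(f"control {control!r} not among conditions")
    n, k = data.shape

    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    f_stat = (ss_cond / df_cond) / ms_err if ms_err > 0 else 0.0
    p_anova = float(stats.f.sf(f_stat, df_cond, df_err)) if ms_err > 0 else (
        1.0 if ss_cond == 0 else 0.0)

    # many-to-one contrasts on the pooled within-subject error (classical
    # Dunnett): every contrast shares MS_error, so the null joint law is
    # multivariate t with correlation 1/2 and df_err, and for k = 2 the
    # statistic coincides with the paired t
    ctrl_idx = condition_ids.index(control)
    others = [i for i in range(k) if i != ctrl_idx]
    t_obs, p_unadj = [], []
    for i in others:
        diff_mean = data[:, i].mean() - data[:, ctrl_idx].mean()
        if ms_err > 0:
            t = diff_mean / np.sqrt(2.0 * ms_err / n)
            p = 2.0 * stats.t.sf(abs(t), df_err)
        else:
            t = 0.0 if diff_mean == 0 else float(np.inf * np.sign(diff_mean))
            p = 1.0 if diff_mean == 0 else 0.0
        t_obs.append(float(t))
        p_unadj.append(float(p))
    t_obs = np.asarray(t_obs)
    p_adj = _dunnett_adjusted_p(t_obs, df_err, n_draws=n_draws, seed=seed)
    p_adj = np.maximum(p_adj, p_unadj)  # adjustment can never help

    return dict(
        F=float(f_stat), df=(df_cond, df_err), p_anova=p_anova,
        comparisons=[dict(condition=condition_ids[i], t=float(t),
                          p_unadjusted=float(pu), p_adjusted=float(pa))
                     for i, t, pu, pa in zip(others, t_obs, p_unadj, p_adj)])


@dataclass
class BlandAltmanResult:
    """Agreement between two paired measurement series."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int
    t_bias: float
    p_bias: float


def bland_altman(x_single, x_dual) -> BlandAltmanResult:
    """Bland-Altman agreement of paired series (differences single - dual).

    A positive bias means the first series runs higher than the second;
    limits of agreement are bias +/- 1.96 SD of the differences.
    """
    x = np.asarray(x_single, dtype=float)
    y = np.asarray(x_dual, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need paired 1-D series with n >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t, p = (0.0, 1.0) if bias == 0 else (float(np.inf * np.sign(bias)), 0.0)
    else:
        t = bias / (sd / np.sqrt(len(d)))
        p = float(2.0 * stats.t.sf(abs(t), len(d) - 1))
    return BlandAltmanResult(bias=bias, sd=sd, loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd, n=len(d),
                             t_bias=float(t), p_bias=p)


def shapiro_flag(values) -> float:
    """Shapiro-Wilk p-value, reported for transparency without gating."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or values.std() == 0:
        return float("nan")
    return float(stats.shapiro(values).pvalue)
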