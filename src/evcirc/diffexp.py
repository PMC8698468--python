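"""Negative-binomial differential expression with a disease-status + sex design.

The engine is a deliberately transparent NB-Wald procedure: median-of-ratios
size factors, gene-wise method-of-moments dispersion with a floor, an NB
log-link GLM (iteratively reweighted least squares via statsmodels) with
status and sex covariates, a Wald test on the contrast coefficient, and
Benjamini-Hochberg adjustment across tested transcripts. There is no fold
change shrinkage, independent filtering or outlier replacement.

Transcripts detected (>= 1 read in >= 1 pool) in both contrast groups are
tested; transcripts detected in exactly one group are routed to the
group-exclusive caller, which reports a moderated descriptive fold change
and no adjusted p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from evcirc.io import InputError

LOG2 = np.log(2.0)

DISPERSION_FLOOR = 0.01
DISPERSION_CEIL = 20.0


class DesignError(ValueError):
    """Non-estimable design matrix or missing contrast levels."""


@dataclass(frozen=True)
class DesignSpec:
    """Per-pool factors and the status contrast to test.

    ``status`` and ``sex`` are indexed by pool name; ``contrast`` is the
    ordered pair ``(numerator_level, denominator_level)`` of status levels,
    so a positive log2 fold change means higher expression in the first
    level.
    """

    status: pd.Series
    sex: pd.Series
    contrast: tuple[str, str]

    @classmethod
    def from_metadata(cls, metadata: pd.DataFrame, contrast: tuple[str, str]) -> "DesignSpec":
        return cls(metadata["status"], metadata["sex"], contrast)

    def validate(self) -> None:
        for level in self.contrast:
            if level not in set(self.status):
                raise DesignError(f"contrast level {level!r} absent from status factor")
        if self.contrast[0] == self.contrast[1]:
            raise DesignError("contrast levels must differ")

    def pools(self) -> pd.Index:
        """Pools belonging to the two contrast groups, in metadata order."""
        return self.status.index[self.status.isin(self.contrast)]

    def design_matrix(self) -> pd.DataFrame:
        """Intercept + status indicator (numerator level) + sex dummies."""
        self.validate()
        pools = self.pools()
        X = pd.DataFrame({"intercept": 1.0}, index=pools)
        X["status"] = (self.status.loc[pools] == self.contrast[0]).astype(float)
        sex_levels = sorted(set(self.sex.loc[pools]))
        for level in sex_levels[1:]:
            X[f"sex_{level}"] = (self.sex.loc[pools] == level).astype(float)
        if np.linalg.matrix_rank(X.values) < X.shape[1]:
            raise DesignError("design matrix is rank deficient (~status + sex not estimable)")
        return X


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios scaling factors (geometric-mean reference).

    The reference is the per-transcript geometric mean over transcripts with
    all-positive counts; each pool's factor is the median ratio of its counts
    to the reference. When no transcript is positive in every pool the
    factors fall back to library-size ratios, with a warning.
    """
    k = counts.to_numpy(dtype=float)
    positive = (k > 0).all(axis=1)
    if positive.sum() == 0:
        warnings.warn(
            "no transcript with positive counts in all pools; "
            "falling back to library-size ratios",
            stacklevel=2,
        )
        lib = k.sum(axis=0)
        ok = lib > 0
        sf = np.ones_like(lib)
        if ok.any():
            sf[ok] = lib[ok] / np.exp(np.mean(np.log(lib[ok])))
        # pools with an empty library get a neutral factor of 1
    else:
        logk = np.log(k[positive])
        ref = np.exp(logk.mean(axis=1))
        sf = np.median(k[positive] / ref[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _mom_dispersion(q: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Gene-wise method-of-moments dispersion from normalized counts.

    Within each status group the excess of the sample variance over the
    sample mean, relative to the squared mean, estimates the NB dispersion;
    group estimates are pooled weighted by their degrees of freedom and
    clipped to [DISPERSION_FLOOR, DISPERSION_CEIL].
    """
    n_genes = q.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for g in np.unique(groups):
        cols = groups == g
        ng = int(cols.sum())
        if ng < 2:
            continue
        m = q[:, cols].mean(axis=1)
        v = q[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_g = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        num += (ng - 1) * alpha_g
        den += ng - 1
    alpha = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEIL)


def detected_mask(counts: pd.DataFrame, pools) -> pd.Series:
    return (counts[pools] >= 1).any(axis=1)


def nb_wald(counts: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """NB GLM Wald test of the status contrast for transcripts shared by both groups.

    Returns a table indexed by transcript id with columns ``baseMean``
    (mean normalized count over the contrast pools), ``log2FC``, ``lfcSE``,
    ``pvalue`` and BH-adjusted ``padj``. The Wald statistic is referred to a
    t distribution with the residual degrees of freedom, a small-sample
    guard for the 4-pools-per-group design.
    """
    design.validate()
    pools = design.pools()
    X = design.design_matrix()
    sub = counts[pools]
    pools_a = design.status.index[design.status == design.contrast[0]]
    pools_b = design.status.index[design.status == design.contrast[1]]
    shared = detected_mask(counts, pools_a) & detected_mask(counts, pools_b)
    sub = sub.loc[shared]
    if len(sub) == 0:
        return pd.DataFrame(columns=["baseMean", "log2FC", "lfcSE", "pvalue", "padj"])

    sf = size_factors(sub)
    offset = np.log(sf.values)
    q = sub.to_numpy(dtype=float) / sf.values[None, :]
    alpha = _mom_dispersion(q, design.status.loc[pools].to_numpy())
    Xv = X.values
    df_resid = Xv.shape[0] - Xv.shape[1]
    coef_i = list(X.columns).index("status")

    log2fc = np.full(len(sub), np.nan)
    se = np.full(len(sub), np.nan)
    pval = np.full(len(sub), np.nan)
    base_mean = q.mean(axis=1)
    y_all = sub.to_numpy(dtype=float)
    for i in range(len(sub)):
        family = sm.families.NegativeBinomial(alpha=float(alpha[i]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y_all[i], Xv, family=family, offset=offset).fit(maxiter=200)
            beta = res.params[coef_i]
            bse = res.bse[coef_i]
        except Exception:
            continue
        if not np.isfinite(beta) or not np.isfinite(bse) or bse == 0:
            continue
        log2fc[i] = beta / LOG2
        se[i] = bse / LOG2
        t = beta / bse
        pval[i] = 2.0 * stats.t.sf(abs(t), df=max(df_resid, 1))

    out = pd.DataFrame(
        {"baseMean": base_mean, "log2FC": log2fc, "lfcSE": se, "pvalue": pval},
        index=sub.index,
    )
    tested = out["pvalue"].notna()
    padj = np.full(len(out), np.nan)
    if tested.sum() > 0:
        padj[tested.values] = multipletests(out.loc[tested, "pvalue"].values, method="fdr_bh")[1]
    out["padj"] = padj
    return out


def call_de(
    de_table: pd.DataFrame, fc_threshold: float = 1.5, p_threshold: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Label up/down/not-DE calls and summarize counts.

    A transcript is called up when log2FC > log2(fc_threshold) and raw
    p < p_threshold (down symmetrically); the counts of calls that also
    reach adjusted p < p_threshold are reported separately in the summary.
    """
    lfc_cut = np.log2(fc_threshold)
    out = de_table.copy()
    call = np.array(["not-DE"] * len(out), dtype=object)
    ok_p = out["pvalue"] < p_threshold
    call[(out["log2FC"] > lfc_cut) & ok_p] = "up"
    call[(out["log2FC"] < -lfc_cut) & ok_p] = "down"
    call[out["pvalue"].isna()] = "not-tested"
    out["call"] = call
    ok_padj = out["padj"] < p_threshold
    summary = {
        "n_tested": int(out["pvalue"].notna().sum()),
        "n_up": int((call == "up").sum()),
        "n_down": int((call == "down").sum()),
        "n_up_padj": int(((call == "up") & ok_padj).sum()),
        "n_down_padj": int(((call == "down") & ok_padj).sum()),
    }
    return out, summary


def call_exclusive(
    counts: pd.DataFrame, metadata: pd.DataFrame, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Group-exclusive transcripts for one contrast, with descriptive fold changes.

    A transcript is exclusive to a group when it has >= 1 read in >= 1 of the
    group's pools and zero reads in every pool of the other group. Because
    the NB likelihood has no finite maximum for a group of structural zeros,
    the reported log2 fold change is a moderated descriptive estimate
    (pseudocount 0.5 on the group means of normalized counts); no p-value or
    adjusted p-value is attached.
    """
    pools_a = metadata.index[metadata["status"] == contrast[0]]
    pools_b = metadata.index[metadata["status"] == contrast[1]]
    if len(pools_a) == 0 or len(pools_b) == 0:
        raise InputError("both contrast groups need pools")
    pools = pools_a.append(pools_b)
    sub = counts[pools]
    sf = size_factors(sub)
    q = sub / sf
    det_a = detected_mask(counts, pools_a)
    det_b = detected_mask(counts, pools_b)
    excl = (det_a & ~det_b) | (det_b & ~det_a)
    q = q.loc[excl]
    m_a = q[pools_a].mean(axis=1)
    m_b = q[pools_b].mean(axis=1)
    out = pd.DataFrame(
        {
            "baseMean": q.mean(axis=1),
            "log2FC": np.log2((m_a + 0.5) / (m_b + 0.5)),
            "lfcSE": np.nan,
            "pvalue": np.nan,
            "padj": np.nan,
            "call": np.where(det_a.loc[q.index], f"exclusive-{contrast[0]}", f"exclusive-{contrast[1]}"),
        },
        index=q.index,
    )
    return out


def rank_candidates(
    de_table: pd.DataFrame,
    k_shared: int = 5,
    host_genes: pd.Series | None = None,
) -> pd.DataFrame:
    """Candidate short-list: best shared transcripts plus strongest exclusives.

    The ``k_shared`` shared transcripts with the smallest adjusted p-value
    (ties broken by ascending \\|log2FC\\| then id) are listed first, followed
    by all group-exclusive transcripts ranked by descending base mean.
    """
    table = de_table.copy()
    is_excl = table["call"].astype(str).str.startswith("exclusive-")
    shared = table.loc[~is_excl & table["padj"].notna()].copy()
    shared["_abs_lfc"] = shared["log2FC"].abs()
    shared["_id"] = shared.index
    shared = shared.sort_values(["padj", "_abs_lfc", "_id"], kind="mergesort").head(k_shared)
    shared = shared.drop(columns=["_abs_lfc", "_id"])
    excl = table.loc[is_excl].sort_values("baseMean", ascending=False, kind="mergesort")
    picked = pd.concat([shared, excl])
    expressed_in = np.where(
        picked["call"].astype(str).str.startswith("exclusive-"),
        picked["call"].astype(str).str.replace("exclusive-", "", regex=False),
        "both",
    )
    out = pd.DataFrame(
        {
            "position": picked.index,
            "gene_symbol": host_genes.reindex(picked.index).fillna("NA").values
            if host_genes is not None
            else "NA",
            "expressed_in": expressed_in,
            "log2FC": picked["log2FC"].round(2).values,
            "padj": picked["padj"].values,
        }
    ).reset_index(drop=True)
    return out
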