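"""Ploidy-effect calling, FDR control and factor dissection.

The central comparison: for each trait (environment x fitness component)
and each species separately, a single haploid measure per strain (the mean
of its two mating-type means) is compared to the strain's diploid measure
across strains with a two-tailed homoscedastic Student's t-test; the
resulting p-values are corrected by Benjamini-Hochberg FDR within the
species, at alpha = 0.05 by default. The ploidy effect is the mean
haploid-minus-diploid difference on the LSC scale.

A trait's effect is *conserved* when it is significant with the same sign
in both species. Two dissection rules attribute effects to molecular
factors: the **cell-size** rule calls a trait size-dependent only when the
large-vs-small comparison is significant in haploids *and* diploids with
concordant direction; the **mating-type** rule calls a trait MAT-dependent
when at least one MAT-hemizygous diploid differs significantly from the
normal heterozygous diploid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import StrainMeta

__all__ = [
    "TTestResult",
    "haploid_score",
    "ttest_homoscedastic",
    "bh_fdr",
    "ploidy_effect_table",
    "per_strain_effect_matrix",
    "conserved_effects",
    "fraction_significant_environments",
    "size_dependence_table",
    "size_dependence_call",
    "mat_dependence_table",
    "mat_dependence_call",
]


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def haploid_score(
    mat_a_reps: Sequence[float], mat_alpha_reps: Sequence[float]
) -> tuple[float, tuple[str, ...]]:
    """Single haploid measure for one strain and trait.

    Mean of the two mating-type means. If only one mating type was
    measured, its mean is used and the result carries a
    ``single_mating_type`` flag; with neither, NaN.
    """
    means = []
    for reps in (mat_a_reps, mat_alpha_reps):
        arr = np.asarray(reps, dtype=float)
        arr = arr[~np.isnan(arr)]
        means.append(float(arr.mean()) if arr.size else np.nan)
    present = [m for m in means if not np.isnan(m)]
    if not present:
        return float("nan"), ("missing",)
    if len(present) == 1:
        return present[0], ("single_mating_type",)
    return float(np.mean(present)), ()


def ttest_homoscedastic(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-tailed pooled-variance (homoscedastic) two-sample t-test.

    Requires at least two observations per group. A zero pooled variance is
    degenerate: p = 1 if the means are equal, else the p -> 0 limit, with
    ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    df = x.size + y.size - 2
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled == 0.0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, p=1.0, df=df, degenerate=True)
        t = np.inf if x.mean() > y.mean() else -np.inf
        return TTestResult(t=float(t), p=0.0, df=df, degenerate=True)
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=df)


def bh_fdr(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR.

    Returns ``(q_values, reject)`` aligned with the input. NaN p-values are
    excluded from the family and yield NaN q / False reject. The rejection
    set is the largest k with ``p_(k) <= k * alpha / m``.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return q, reject
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rej, qvals, _, _ = multipletests(p[mask], alpha=alpha, method="fdr_bh")
    q[mask] = qvals
    reject[mask] = rej
    return q, reject


def _ttest_matrix(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise pooled-variance t-tests with NaN omission.

    X (nx, T) vs Y (ny, T); returns (t, p, n_x, n_y) per column. Columns
    with fewer than two observations in either group give NaN. Zero pooled
    variance follows the degenerate convention of
    :func:`ttest_homoscedastic`.
    """
    nx = np.sum(~np.isnan(X), axis=0)
    ny = np.sum(~np.isnan(Y), axis=0)
    ok = (nx >= 2) & (ny >= 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mx = np.nanmean(X, axis=0)
        my = np.nanmean(Y, axis=0)
        ssx = np.nansum((X - mx) ** 2, axis=0)
        ssy = np.nansum((Y - my) ** 2, axis=0)
    df = nx + ny - 2
    t = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.where(ok, (ssx + ssy) / np.maximum(df, 1), np.nan)
        se = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
        t_ok = (mx - my) / se
    normal = ok & (pooled > 0)
    t[normal] = t_ok[normal]
    p[normal] = 2.0 * stats.t.sf(np.abs(t_ok[normal]), df[normal])
    degen = ok & (pooled == 0)
    if np.any(degen):
        eq = degen & (mx == my)
        t[eq], p[eq] = 0.0, 1.0
        ne = degen & (mx != my)
        t[ne] = np.where(mx[ne] > my[ne], np.inf, -np.inf)
        p[ne] = 0.0
    return t, p, nx, ny


def _species_table(meta: Union[pd.DataFrame, Iterable[StrainMeta]]) -> pd.Series:
    if isinstance(meta, pd.DataFrame):
        # Tolerate per-well metadata: one species entry per strain.
        return (
            meta[["strain_id", "species"]]
            .drop_duplicates()
            .set_index("strain_id")["species"]
        )
    return pd.Series({s.strain_id: s.species for s in meta}, name="species")


def _haploid_diploid_matrices(
    matrix: pd.DataFrame, strains: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain haploid-score and diploid matrices (strains x traits).

    The haploid score averages the two mating-type rows (each already a
    replicate mean); a strain with a single measured mating type
    contributes that one. The diploid measure is the normal heterozygous
    (a/alpha) diploid row; MAT-hemizygous rows are never part of the
    ploidy comparison.
    """
    hap = matrix.xs("haploid", level="ploidy")
    hap = hap.groupby(level="strain_id").mean()  # mean over mating types, NaN-aware
    dip = matrix.xs("diploid", level="ploidy")
    dip = dip[dip.index.get_level_values("mating_type") == "a_alpha"]
    dip = dip.groupby(level="strain_id").mean()
    strains = [s for s in strains if s in hap.index or s in dip.index]
    return hap.reindex(strains), dip.reindex(strains)


def ploidy_effect_table(
    matrix: pd.DataFrame,
    meta: Union[pd.DataFrame, Iterable[StrainMeta]],
    alpha: float = 0.05,
    min_strains: int = 2,
) -> pd.DataFrame:
    """Species-level ploidy-effect records for every trait.

    Parameters
    ----------
    matrix : DataFrame
        LSC trait matrix (rows ``(strain_id, ploidy, mating_type)``,
        columns ``(environment, component)``).
    meta : DataFrame or iterable of StrainMeta
        Must map every strain to its species.
    alpha : float
        FDR level; BH correction is applied within each species over all
        its traits.
    min_strains : int
        Minimum strains per ploidy group for a trait to be tested; traits
        below it are reported untested (NaN statistics) with a warning.

    Returns
    -------
    DataFrame with one row per species x environment x component:
    ``haploid_mean, diploid_mean, effect`` (= haploid - diploid), ``t, p,
    q, significant, n_haploid, n_diploid``.
    """
    species_of = _species_table(meta)
    records = []
    for species in sorted(species_of.unique()):
        strains = sorted(species_of.index[species_of == species])
        hap, dip = _haploid_diploid_matrices(matrix, strains)
        traits = matrix.columns
        H = hap.reindex(columns=traits).to_numpy(dtype=float)
        D = dip.reindex(columns=traits).to_numpy(dtype=float)
        t, p, nx, ny = _ttest_matrix(H, D)
        too_few = (nx < min_strains) | (ny < min_strains)
        if np.any(too_few & ~np.isnan(p)):
            p = np.where(too_few, np.nan, p)
        if np.any(too_few):
            warnings.warn(
                f"{int(too_few.sum())} trait(s) skipped for {species}: "
                f"fewer than {min_strains} strains per ploidy"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            hmean = np.nanmean(H, axis=0)
            dmean = np.nanmean(D, axis=0)
        q, rej = bh_fdr(p, alpha=alpha)
        for j, (env, comp) in enumerate(traits):
            records.append(
                dict(
                    species=species,
                    environment=env,
                    component=comp,
                    haploid_mean=hmean[j],
                    diploid_mean=dmean[j],
                    effect=hmean[j] - dmean[j],
                    t=t[j],
                    p=p[j],
                    q=q[j],
                    significant=bool(rej[j]),
                    n_haploid=int(nx[j]),
                    n_diploid=int(ny[j]),
                )
            )
    return pd.DataFrame(records)


def per_strain_effect_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-strain ploidy effects: haploid score minus diploid, per trait.

    This strains x traits matrix is the input for pair-similarity and
    clustering analyses of ploidy-environment interactions.
    """
    hap, dip = _haploid_diploid_matrices(
        matrix, sorted(matrix.index.get_level_values("strain_id").unique())
    )
    return hap - dip


def conserved_effects(records: pd.DataFrame) -> pd.DataFrame:
    """Classify cross-species conservation of ploidy effects.

    Expects the output of :func:`ploidy_effect_table` covering both
    species. Returns one row per trait with columns per species plus
    ``conserved`` (significant in both with the same effect sign) and a
    ``classification`` in {both, cerevisiae_only, paradoxus_only, none,
    unclassified} (unclassified = trait untested in one species).
    """
    wide = records.pivot_table(
        index=["environment", "component"],
        columns="species",
        values=["effect", "significant", "p"],
        aggfunc="first",
    )
    out = []
    for trait, row in wide.iterrows():
        e_c = row.get(("effect", "cerevisiae"), np.nan)
        e_p = row.get(("effect", "paradoxus"), np.nan)
        s_c = row.get(("significant", "cerevisiae"), np.nan)
        s_p = row.get(("significant", "paradoxus"), np.nan)
        if pd.isna(row.get(("p", "cerevisiae"), np.nan)) or pd.isna(
            row.get(("p", "paradoxus"), np.nan)
        ):
            cls, conserved = "unclassified", False
        else:
            s_c, s_p = bool(s_c), bool(s_p)
            if s_c and s_p:
                conserved = np.sign(e_c) == np.sign(e_p)
                cls = "both" if conserved else "none"
            elif s_c:
                cls, conserved = "cerevisiae_only", False
            elif s_p:
                cls, conserved = "paradoxus_only", False
            else:
                cls, conserved = "none", False
        out.append(
            dict(
                environment=trait[0],
                component=trait[1],
                effect_cerevisiae=e_c,
                effect_paradoxus=e_p,
                conserved=bool(conserved),
                classification=cls,
            )
        )
    return pd.DataFrame(out)


def fraction_significant_environments(
    records: pd.DataFrame,
    environments: Optional[Sequence[str]] = None,
    mode: str = "any",
) -> float:
    """Fraction of environments showing a significant ploidy effect.

    ``mode="any"`` (default): an environment counts if *any* of its
    component records (either species) is significant. ``mode="all"``:
    every fitness component must have at least one significant record in
    that environment. The denominator is ``environments`` if given, else
    the environments present in ``records``.
    """
    if environments is None:
        environments = sorted(records["environment"].unique())
    if len(environments) == 0:
        return 0.0
    sig = records[records["significant"].astype(bool)]
    n_hit = 0
    all_components = sorted(records["component"].unique())
    for env in environments:
        comps = set(sig.loc[sig["environment"] == env, "component"])
        if mode == "any":
            n_hit += bool(comps)
        elif mode == "all":
            n_hit += set(all_components) <= comps
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return n_hit / len(environments)


def _two_group_frame(df: pd.DataFrame) -> np.ndarray:
    return np.asarray(df, dtype=float)


def size_dependence_table(
    haploid_large: pd.DataFrame,
    haploid_small: pd.DataFrame,
    diploid_large: pd.DataFrame,
    diploid_small: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cell-size dependence calls over a batch of traits.

    Each input is a replicates x traits frame of LSC values (columns must
    match across inputs). The large-vs-small comparison is tested
    independently within haploids and within diploids; BH-FDR runs over
    the whole family (both comparisons, all traits). A trait is called
    size-dependent only when both comparisons are significant *and* the
    effect directions agree.
    """
    traits = haploid_large.columns
    for other in (haploid_small, diploid_large, diploid_small):
        if not traits.equals(other.columns):
            raise ValueError("trait columns must match across the four groups")
    t_h, p_h, *_ = _ttest_matrix(_two_group_frame(haploid_large), _two_group_frame(haploid_small))
    t_d, p_d, *_ = _ttest_matrix(_two_group_frame(diploid_large), _two_group_frame(diploid_small))
    eff_h = np.nanmean(_two_group_frame(haploid_large), axis=0) - np.nanmean(
        _two_group_frame(haploid_small), axis=0
    )
    eff_d = np.nanmean(_two_group_frame(diploid_large), axis=0) - np.nanmean(
        _two_group_frame(diploid_small), axis=0
    )
    q_all, rej_all = bh_fdr(np.concatenate([p_h, p_d]), alpha=alpha)
    T = len(traits)
    q_h, q_d = q_all[:T], q_all[T:]
    r_h, r_d = rej_all[:T], rej_all[T:]
    concordant = np.sign(eff_h) == np.sign(eff_d)
    positive = r_h & r_d & concordant
    direction = np.where(positive, np.sign(eff_h), 0.0)
    return pd.DataFrame(
        dict(
            environment=[t[0] for t in traits],
            component=[t[1] for t in traits],
            effect_haploid=eff_h,
            effect_diploid=eff_d,
            p_haploid=p_h,
            p_diploid=p_d,
            q_haploid=q_h,
            q_diploid=q_d,
            significant_haploid=r_h,
            significant_diploid=r_d,
            positive_call=positive,
            direction=direction,
        )
    )


def size_dependence_call(
    haploid_large: Sequence[float],
    haploid_small: Sequence[float],
    diploid_large: Sequence[float],
    diploid_small: Sequence[float],
    alpha: float = 0.05,
) -> dict:
    """Single-trait cell-size call (FDR family = this trait's two tests)."""
    cols = pd.MultiIndex.from_tuples([("trait", "value")])
    frame = lambda v: pd.DataFrame(np.asarray(v, dtype=float)[:, None], columns=cols)
    table = size_dependence_table(
        frame(haploid_large), frame(haploid_small),
        frame(diploid_large), frame(diploid_small), alpha=alpha,
    )
    return table.iloc[0].to_dict()


def mat_dependence_table(
    hemizygote_a: pd.DataFrame,
    hemizygote_alpha: pd.DataFrame,
    heterozygote: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mating-type-locus dependence calls over a batch of traits.

    Each MAT-hemizygous diploid (a or alpha) is compared to the normal
    heterozygous a/alpha diploid per trait; BH-FDR runs over all traits x
    both comparisons. A trait is MAT-dependent when at least one
    hemizygote differs significantly from the heterozygote.
    """
    traits = heterozygote.columns
    for other in (hemizygote_a, hemizygote_alpha):
        if not traits.equals(other.columns):
            raise ValueError("trait columns must match across groups")
    t_a, p_a, *_ = _ttest_matrix(_two_group_frame(hemizygote_a), _two_group_frame(heterozygote))
    t_al, p_al, *_ = _ttest_matrix(_two_group_frame(hemizygote_alpha), _two_group_frame(heterozygote))
    eff_a = np.nanmean(_two_group_frame(hemizygote_a), axis=0) - np.nanmean(
        _two_group_frame(heterozygote), axis=0
    )
    eff_al = np.nanmean(_two_group_frame(hemizygote_alpha), axis=0) - np.nanmean(
        _two_group_frame(heterozygote), axis=0
    )
    q_all, rej_all = bh_fdr(np.concatenate([p_a, p_al]), alpha=alpha)
    T = len(traits)
    r_a, r_al = rej_all[:T], rej_all[T:]
    positive = r_a | r_al
    # Direction from the stronger (more significant) hemizygote comparison.
    pick_a = np.where(np.isnan(p_al), True, np.nan_to_num(p_a, nan=np.inf) <= np.nan_to_num(p_al, nan=np.inf))
    direction = np.where(positive, np.sign(np.where(pick_a, eff_a, eff_al)), 0.0)
    return pd.DataFrame(
        dict(
            environment=[t[0] for t in traits],
            component=[t[1] for t in traits],
            effect_hemi_a=eff_a,
            effect_hemi_alpha=eff_al,
            p_hemi_a=p_a,
            p_hemi_alpha=p_al,
            q_hemi_a=q_all[:T],
            q_hemi_alpha=q_all[T:],
            significant_hemi_a=r_a,
            significant_hemi_alpha=r_al,
            positive_call=positive,
            direction=direction,
        )
    )


def mat_dependence_call(
    hemizygote_a: Optional[Sequence[float]],
    hemizygote_alpha: Optional[Sequence[float]],
    heterozygote: Sequence[float],
    alpha: float = 0.05,
) -> dict:
    """Single-trait mating-type-locus call.

    At least one hemizygote series is required; a missing one contributes
    no comparison (and cannot trigger a positive call).
    """
    if hemizygote_a is None and hemizygote_alpha is None:
        raise ValueError("at least one hemizygote series required")
    cols = pd.MultiIndex.from_tuples([("trait", "value")])

    def frame(v):
        if v is None:
            return pd.DataFrame(np.full((2, 1), np.nan), columns=cols)
        return pd.DataFrame(np.asarray(v, dtype=float)[:, None], columns=cols)

    table = mat_dependence_table(
        frame(hemizygote_a), frame(hemizygote_alpha), frame(heterozygote), alpha=alpha
    )
    return table.iloc[0].to_dict()
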