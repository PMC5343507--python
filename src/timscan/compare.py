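"""Cross-orthologue fitness-landscape statistics.

A position's mutational profile is the vector of selection coefficients of
its amino-acid substitutions. Landscapes of two orthologues are compared by
Pearson-correlating profiles over sets of position pairs:

- ``identical_wt``: all cross-orthologue pairs sharing the WT residue,
  irrespective of alignment;
- ``aligned``: structurally aligned pairs;
- ``aligned_nonidentical``: aligned pairs with differing WT residues;
- ``fourfold``: pairs occupying the same four-fold symmetry cell
  (quadrant, offset);
- ``null_all_pairs``: every position pair — the null model.

Distributions of R are contrasted by two-sample Kolmogorov-Smirnov tests.
Distributions of fitness effects over structural strata are contrasted by a
permutation test on the beneficial fraction that reassigns whole
per-position profiles to random positions. Transformative mutations —
substitutions to the WT residue of the aligned position in another
orthologue — get their own detrimental-fraction summary.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import AA20, STOP
from .annotate import AlignmentMap, fourfold_index
from .fitness import FitnessLandscape

SET_LABELS = (
    "identical_wt",
    "aligned",
    "aligned_nonidentical",
    "fourfold",
    "null_all_pairs",
)


@dataclasses.dataclass
class PositionProfile:
    """One position's substitution response: s per amino-acid outcome."""

    position: int
    wt_residue: str
    values: pd.Series  # indexed by outcome class


def position_profiles(
    landscape: FitnessLandscape, include_stop: bool = False
) -> dict[int, PositionProfile]:
    """Extract per-position profiles; stop outcomes are excluded by default
    (they measure expression shutdown, not substitution response)."""
    outcomes = list(AA20) + ([STOP] if include_stop else [])
    out: dict[int, PositionProfile] = {}
    for pos in landscape.positions():
        prof = landscape.position_profile(pos).reindex(outcomes)
        out[pos] = PositionProfile(
            position=pos, wt_residue=landscape.wt_aa(pos), values=prof
        )
    return out


def profile_correlation(
    p: PositionProfile,
    q: PositionProfile,
    policy: str = "exclude_both_wt",
    min_shared: int = 3,
) -> float | None:
    """Pearson R between two positions' substitution profiles.

    ``exclude_both_wt`` (default) drops the amino acids that are WT at
    either position, leaving 18-19 shared substitutions;
    ``include_all_20`` keeps the full outcome set. Pairs with fewer than
    ``min_shared`` shared finite values, or zero variance in either vector,
    have no defined R and return None.
    """
    if policy not in ("exclude_both_wt", "include_all_20"):
        raise ValueError(f"unknown WT policy {policy!r}")
    shared = p.values.index.intersection(q.values.index)
    if policy == "exclude_both_wt":
        shared = shared.difference([p.wt_residue, q.wt_residue])
    x = p.values.reindex(shared).to_numpy(dtype=float)
    y = q.values.reindex(shared).to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_shared:
        return None
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def _within_positions(landscape: FitnessLandscape) -> pd.DataFrame:
    """Rank positions within each library (1-based within_position)."""
    pos = (
        landscape.table[["library", "position"]]
        .drop_duplicates()
        .sort_values(["library", "position"])
        .reset_index(drop=True)
    )
    pos["within_position"] = pos.groupby("library").cumcount() + 1
    return pos


def build_position_set(
    landscape_a: FitnessLandscape,
    landscape_b: FitnessLandscape,
    set_label: str,
    alignment: AlignmentMap | None = None,
) -> list[tuple[int, int]]:
    """Enumerate the position pairs of one comparison set."""
    if set_label not in SET_LABELS:
        raise ValueError(f"unknown set label {set_label!r}; one of {SET_LABELS}")
    pos_a = landscape_a.positions()
    pos_b = landscape_b.positions()
    if set_label == "null_all_pairs":
        return [(a, b) for a in pos_a for b in pos_b]
    if set_label == "identical_wt":
        return [
            (a, b)
            for a in pos_a
            for b in pos_b
            if landscape_a.wt_aa(a) == landscape_b.wt_aa(b)
        ]
    if set_label == "fourfold":
        wa = _within_positions(landscape_a)
        wb = _within_positions(landscape_b)
        cell_a = {
            int(r.position): fourfold_index(int(r.library), int(r.within_position))
            for _, r in wa.iterrows()
        }
        cell_b = {
            int(r.position): fourfold_index(int(r.library), int(r.within_position))
            for _, r in wb.iterrows()
        }
        return [(a, b) for a in pos_a for b in pos_b if cell_a[a] == cell_b[b]]
    if alignment is None:
        raise ValueError(f"set {set_label!r} requires an alignment map")
    pairs = [(int(r.pos_a), int(r.pos_b)) for _, r in alignment.pairs.iterrows()]
    pairs = [(a, b) for a, b in pairs if a in set(pos_a) and b in set(pos_b)]
    if set_label == "aligned":
        return pairs
    # aligned_nonidentical
    return [
        (a, b) for a, b in pairs if landscape_a.wt_aa(a) != landscape_b.wt_aa(b)
    ]


@dataclasses.dataclass
class CorrelationDistribution:
    """Profile correlations over one position set."""

    set_label: str
    r_values: np.ndarray
    n_pairs: int
    n_skipped: int = 0
    policy: str = "exclude_both_wt"

    @property
    def mode(self) -> float:
        """Center of the fullest histogram bin over [-1, 1] (20 bins)."""
        hist, edges = np.histogram(self.r_values, bins=20, range=(-1.0, 1.0))
        i = int(np.argmax(hist))
        return float(0.5 * (edges[i] + edges[i + 1]))


def correlation_distribution(
    landscape_a: FitnessLandscape,
    landscape_b: FitnessLandscape,
    pairs: list[tuple[int, int]],
    set_label: str = "aligned",
    policy: str = "exclude_both_wt",
    min_shared: int = 3,
) -> CorrelationDistribution:
    """Vectorized Pearson R over a list of position pairs.

    Pairs with undefined R (too few shared finite values or zero variance)
    are skipped and counted, never imputed.
    """
    if policy not in ("exclude_both_wt", "include_all_20"):
        raise ValueError(f"unknown WT policy {policy!r}")
    aa_index = {aa: i for i, aa in enumerate(AA20)}

    def matrix(landscape):
        positions = landscape.positions()
        pidx = {p: i for i, p in enumerate(positions)}
        m = np.full((len(positions), 20), np.nan)
        piv = landscape.table.pivot_table(
            index="position", columns="outcome", values="s", aggfunc="first"
        )
        for aa in AA20:
            if aa in piv.columns:
                m[[pidx[p] for p in piv.index], aa_index[aa]] = piv[aa].to_numpy()
        wt = np.array([aa_index[landscape.wt_aa(p)] for p in positions])
        return m, wt, pidx

    ma, wta, ia = matrix(landscape_a)
    mb, wtb, ib = matrix(landscape_b)
    pi = np.array([ia[a] for a, _ in pairs], dtype=int)
    pj = np.array([ib[b] for _, b in pairs], dtype=int)
    X = ma[pi]  # (P, 20)
    Y = mb[pj]
    mask = np.isfinite(X) & np.isfinite(Y)
    if policy == "exclude_both_wt":
        rows = np.arange(len(pairs))
        mask[rows, wta[pi]] = False
        mask[rows, wtb[pj]] = False
    n = mask.sum(axis=1)
    Xm = np.where(mask, X, 0.0)
    Ym = np.where(mask, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Xm.sum(1) / n
        my = Ym.sum(1) / n
        dx = np.where(mask, X - mx[:, None], 0.0)
        dy = np.where(mask, Y - my[:, None], 0.0)
        sxx = (dx * dx).sum(1)
        syy = (dy * dy).sum(1)
        r = (dx * dy).sum(1) / np.sqrt(sxx * syy)
    valid = (n >= min_shared) & (sxx > 0) & (syy > 0) & np.isfinite(r)
    return CorrelationDistribution(
        set_label=set_label,
        r_values=r[valid],
        n_pairs=len(pairs),
        n_skipped=int(len(pairs) - valid.sum()),
        policy=policy,
    )


def compare_distributions_ks(
    dist_1: CorrelationDistribution | np.ndarray,
    dist_2: CorrelationDistribution | np.ndarray,
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test between correlation distributions."""
    x = dist_1.r_values if isinstance(dist_1, CorrelationDistribution) else np.asarray(dist_1)
    y = dist_2.r_values if isinstance(dist_2, CorrelationDistribution) else np.asarray(dist_2)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both distributions must be non-empty")
    if min(len(x), len(y)) < 5:
        warnings.warn("fewer than 5 values in a sample; KS p-value is unreliable")
    res = stats.ks_2samp(x, y)
    return float(res.statistic), float(res.pvalue)


def _substitution_stats(landscape: FitnessLandscape):
    """Per-position beneficial and valid substitution counts (19 per position:
    stop and the WT class excluded)."""
    tab = landscape.table
    sub = tab[(tab.outcome != STOP) & (tab.outcome != tab.wt_aa) & tab.s.notna()]
    grouped = sub.groupby("position")["s"]
    positions = np.array(sorted(tab.position.unique()))
    b = np.zeros(len(positions))
    m = np.zeros(len(positions))
    beneficial = grouped.apply(lambda s: int((s > 0).sum()))
    valid = grouped.size()
    for i, p in enumerate(positions):
        b[i] = beneficial.get(p, 0)
        m[i] = valid.get(p, 0)
    return positions, b, m


@dataclasses.dataclass
class PermutationTestResult:
    observed: float
    p_value: float
    n_perm: int
    null_mean: float
    alternative: str


def beneficial_fraction_test(
    landscape: FitnessLandscape,
    subset,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationTestResult:
    """Permutation test on a position subset's beneficial fraction.

    The observed statistic is the fraction of the subset's substitutions
    (19 per position) with s > 0. The null reassigns whole per-position
    profiles to uniformly random positions ``n_perm`` times — equivalently,
    draws random position subsets of the same size — and recomputes the
    fraction. P-values count the null values at least as extreme as the
    observed one (two-sided: absolute deviation from the null mean), with
    the add-one correction so p is never 0.
    """
    positions, b, m = _substitution_stats(landscape)
    subset = np.asarray(sorted(set(int(p) for p in subset)))
    pset = set(positions.tolist())
    if not set(subset.tolist()) <= pset:
        raise ValueError("subset contains positions absent from the landscape")
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    if len(subset) == len(positions):
        raise ValueError("subset equals all positions: no null contrast")
    idx = np.searchsorted(positions, subset)
    k = len(subset)
    observed = float(b[idx].sum() / m[idx].sum())
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, len(positions))), axis=1)[:, :k]
    null = b[order].sum(axis=1) / m[order].sum(axis=1)
    if alternative == "greater":
        n_ext = int((null >= observed - 1e-12).sum())
    elif alternative == "less":
        n_ext = int((null <= observed + 1e-12).sum())
    elif alternative == "two-sided":
        center = null.mean()
        n_ext = int(
            (np.abs(null - center) >= np.abs(observed - center) - 1e-12).sum()
        )
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + n_ext) / (n_perm + 1)
    return PermutationTestResult(
        observed=observed,
        p_value=float(p),
        n_perm=n_perm,
        null_mean=float(null.mean()),
        alternative=alternative,
    )


@dataclasses.dataclass
class TransformativeSet:
    """Substitutions to another orthologue's WT residue at aligned positions."""

    mutations: pd.DataFrame  # orthologue, position, target, s
    all_s: np.ndarray

    @property
    def s_values(self) -> np.ndarray:
        return self.mutations.s.to_numpy(dtype=float)


def transformative_analysis(
    landscape_a: FitnessLandscape,
    landscape_b: FitnessLandscape,
    alignment: AlignmentMap,
    detrimental_threshold: float = -0.5,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[TransformativeSet, dict]:
    """Collect transformative mutations and compare them to all mutations.

    For every aligned pair with differing WT residues, the mutation in A to
    B's WT residue (and symmetrically in B to A's) is transformative. The
    summary reports the detrimental fraction (s below the threshold), a KS
    test of the transformative s values against all substitution s values,
    and a permutation p for the detrimental fraction under random
    same-sized mutation draws.
    """
    rows = []
    for _, pr in alignment.pairs.iterrows():
        a, b = int(pr.pos_a), int(pr.pos_b)
        try:
            wt_a, wt_b = landscape_a.wt_aa(a), landscape_b.wt_aa(b)
        except KeyError:
            continue
        if wt_a == wt_b:
            continue
        for land, pos, target in (
            (landscape_a, a, wt_b),
            (landscape_b, b, wt_a),
        ):
            prof = land.position_profile(pos)
            s = prof.get(target, np.nan)
            if np.isfinite(s):
                rows.append(
                    {
                        "orthologue": land.orthologue,
                        "position": pos,
                        "target": target,
                        "s": float(s),
                    }
                )
    mutations = pd.DataFrame(rows, columns=["orthologue", "position", "target", "s"])

    def all_substitutions(land):
        t = land.table
        sub = t[(t.outcome != STOP) & (t.outcome != t.wt_aa) & t.s.notna()]
        return sub.s.to_numpy(dtype=float)

    all_s = np.concatenate(
        [all_substitutions(landscape_a), all_substitutions(landscape_b)]
    )
    tset = TransformativeSet(mutations=mutations, all_s=all_s)
    summary: dict = {"n_transformative": len(mutations)}
    if len(mutations):
        s = tset.s_values
        observed = float(np.mean(s < detrimental_threshold))
        summary["detrimental_fraction"] = observed
        d, p_ks = compare_distributions_ks(s, all_s)
        summary["ks"] = {"D": d, "p": p_ks}
        rng = np.random.default_rng(seed)
        draws = rng.choice(all_s, size=(n_perm, len(s)), replace=True)
        null = (draws < detrimental_threshold).mean(axis=1)
        n_le = int((null <= observed + 1e-12).sum())
        n_ge = int((null >= observed - 1e-12).sum())
        p = min(1.0, 2.0 * min((1 + n_le) / (n_perm + 1), (1 + n_ge) / (n_perm + 1)))
        summary["permutation_p"] = float(p)
    return tset, summary


def mean_profile_correlation(
    landscape_a: FitnessLandscape,
    landscape_b: FitnessLandscape,
    pairs: list[tuple[int, int]],
    policy: str = "exclude_both_wt",
) -> float:
    """Mean Pearson R over a pair set (replicate-baseline helper)."""
    dist = correlation_distribution(landscape_a, landscape_b, pairs, policy=policy)
    if dist.r_values.size == 0:
        raise ValueError("no defined correlations over the given pairs")
    return float(dist.r_values.mean())
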