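"""Raw fitness and stop-normalized selection coefficients.

Raw fitness ``w`` of a variant is the ordinary-least-squares slope of
log2(N_mut(t) / N_WT(t)) against time in WT doublings. Within each
10-position library the mean raw fitness of all stop-codon outcomes,
``w_stop``, anchors the scale: the selection coefficient is

    s = -w / w_stop,

the unique linear map with s(0) = 0 and mean stop-codon s = -1. A variant
with s = 0 grows like WT; s = -1 matches the average null (stop) allele;
s > 0 is beneficial.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AA_TO_CODONS, STOP
from .counts import CountTimeSeries
from .design import LibraryDesign, _has_mmei

LANDSCAPE_COLUMNS = [
    "orthologue",
    "library",
    "position",
    "wt_aa",
    "outcome",
    "w",
    "s",
    "flags",
]

#: Poor-coverage mutations excluded from the original three-orthologue scan
#: (orthologue, WT residue, position, substituted residue).
POOR_COVERAGE_MUTATIONS = (
    ("SsIGPS", "A", 174, "W"),
    ("TmIGPS", "I", 131, "M"),
    ("TmIGPS", "I", 178, "C"),
    ("TmIGPS", "I", 178, "W"),
    ("TtIGPS", "G", 78, "M"),
    ("TtIGPS", "L", 153, "C"),
    ("TtIGPS", "L", 153, "Y"),
)


@dataclasses.dataclass
class RawFitness:
    """OLS slope of the log2 mutant/WT abundance ratio per WT doubling."""

    w: float | None
    n_timepoints: int
    r_squared: float | None
    flags: tuple[str, ...] = ()


def raw_fitness(
    series_mut: np.ndarray, series_wt: np.ndarray, times: np.ndarray
) -> RawFitness:
    """Estimate raw fitness from one variant's count trajectory.

    Time points where either the mutant or the WT count is zero carry no
    defined log-ratio and are dropped; fewer than two usable points yields a
    ``low_coverage`` flag and no slope.
    """
    mut = np.asarray(series_mut, dtype=float)
    wt = np.asarray(series_wt, dtype=float)
    t = np.asarray(times, dtype=float)
    if not (len(mut) == len(wt) == len(t)):
        raise ValueError("series and times must have equal length")
    usable = (mut > 0) & (wt > 0)
    n = int(usable.sum())
    if n < 2:
        return RawFitness(w=None, n_timepoints=n, r_squared=None, flags=("low_coverage",))
    y = np.log2(mut[usable] / wt[usable])
    x = t[usable]
    xc = x - x.mean()
    yc = y - y.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return RawFitness(w=None, n_timepoints=n, r_squared=None, flags=("low_coverage",))
    slope = float(xc @ yc) / denom
    ss_tot = float(yc @ yc)
    if ss_tot == 0.0:
        r2 = 1.0
    else:
        resid = yc - slope * xc
        r2 = 1.0 - float(resid @ resid) / ss_tot
    return RawFitness(w=slope, n_timepoints=n, r_squared=r2)


def stop_normalize(raw_w: dict[str, float], stop_outcomes: tuple[str, ...] = (STOP,)):
    """Normalize one library's raw fitness values by its mean stop fitness.

    Returns ``(s_map, w_stop_mean)``. If the mean stop raw fitness is not
    negative the selection failed (stops did not deplete) and the library is
    unnormalizable: raises ``ValueError``.
    """
    stops = [w for o, w in raw_w.items() if o in stop_outcomes and w is not None]
    if not stops:
        raise ValueError("no stop-codon raw fitness available for normalization")
    w_stop = float(np.mean(stops))
    if w_stop >= 0:
        raise ValueError(
            f"mean stop raw fitness {w_stop:.3g} is non-negative; library unnormalizable"
        )
    s_map = {o: (None if w is None else -w / w_stop) for o, w in raw_w.items()}
    return s_map, w_stop


@dataclasses.dataclass
class FitnessLandscape:
    """Selection coefficients over (library, position, outcome) cells.

    ``table`` columns: orthologue, library, position, wt_aa, outcome, w, s,
    flags (comma-joined; empty when clean). ``stop_means`` maps library to
    the mean stop raw fitness used for its normalization. ``exclusions``
    is the ledger of removed cells with their reasons.
    """

    table: pd.DataFrame
    stop_means: dict[int, float] = dataclasses.field(default_factory=dict)
    exclusions: list[dict] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(LANDSCAPE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"landscape table missing columns: {sorted(missing)}")

    @property
    def orthologue(self) -> str:
        return str(self.table.orthologue.iloc[0])

    def included(self) -> pd.DataFrame:
        """Rows carrying a selection coefficient (excluded cells have s=NaN)."""
        return self.table[self.table.s.notna()]

    def s_values(self) -> np.ndarray:
        return self.included().s.to_numpy(dtype=float)

    def positions(self) -> tuple[int, ...]:
        return tuple(int(p) for p in sorted(self.table.position.unique()))

    def position_profile(
        self, position: int, outcomes: tuple[str, ...] | None = None
    ) -> pd.Series:
        """s values of one position as a Series indexed by outcome class."""
        sub = self.table[self.table.position == position]
        if sub.empty:
            raise KeyError(f"position {position} not in landscape")
        prof = sub.set_index("outcome").s
        if outcomes is not None:
            prof = prof.reindex(list(outcomes))
        return prof

    def wt_aa(self, position: int) -> str:
        sub = self.table[self.table.position == position]
        if sub.empty:
            raise KeyError(f"position {position} not in landscape")
        return str(sub.wt_aa.iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FitnessLandscape":
        df = pd.read_csv(
            path, sep="\t", na_values=["NA"], keep_default_na=False
        )
        df["flags"] = df["flags"].fillna("")  # note: .flags is reserved on DataFrames
        return cls(table=df)

    def write_exclusion_ledger(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.exclusions, indent=1))


def estimate_landscape(
    counts: CountTimeSeries,
    design: LibraryDesign,
    pseudocount: float = 0.0,
) -> FitnessLandscape:
    """Estimate raw fitness and selection coefficients for every cell.

    ``pseudocount`` is added to every count before the log-ratio regression
    (default 0: zero-count time points are dropped instead).
    """
    t = np.asarray(counts.timepoints)
    agg = counts.aggregate_outcomes()
    rows = []
    stop_means: dict[int, float] = {}
    exclusions: list[dict] = []
    for lib in design.libraries:
        wt_series = agg.wt_series(lib) + pseudocount
        lib_pos = design.library_positions(lib)
        raw_by_cell: dict[tuple[int, str], RawFitness] = {}
        for _, prow in lib_pos.iterrows():
            pos = int(prow.position)
            present = set(
                agg.counts[(agg.counts.library == lib) & (agg.counts.position == pos)]
                .outcome
            )
            for outcome in sorted(present):
                mut = agg.variant_series(lib, pos, outcome) + pseudocount
                raw_by_cell[(pos, outcome)] = raw_fitness(mut, wt_series, t)
        stop_w = [
            rf.w
            for (pos, o), rf in raw_by_cell.items()
            if o == STOP and rf.w is not None
        ]
        w_stop = float(np.mean(stop_w)) if stop_w else np.nan
        normalizable = bool(stop_w) and w_stop < 0
        if normalizable:
            stop_means[lib] = w_stop
        for (pos, outcome), rf in sorted(raw_by_cell.items()):
            flags = list(rf.flags)
            if rf.w is None:
                s = np.nan
                exclusions.append(
                    {
                        "orthologue": design.orthologue,
                        "library": lib,
                        "position": pos,
                        "outcome": outcome,
                        "reason": "low_coverage",
                    }
                )
            elif not normalizable:
                s = np.nan
                flags.append("unnormalizable")
            else:
                s = -rf.w / w_stop
            rows.append(
                {
                    "orthologue": design.orthologue,
                    "library": lib,
                    "position": pos,
                    "wt_aa": design.wt_aa_at(pos),
                    "outcome": outcome,
                    "w": np.nan if rf.w is None else rf.w,
                    "s": s,
                    "flags": ",".join(flags),
                }
            )
    return FitnessLandscape(
        table=pd.DataFrame(rows, columns=LANDSCAPE_COLUMNS),
        stop_means=stop_means,
        exclusions=exclusions,
    )


def mmei_forced_cells(design: LibraryDesign) -> list[tuple[int, int, str]]:
    """Cells whose every encoding codon creates an MmeI site in context.

    Such cells cannot be observed at all (every read carrying them is
    filtered), so their fitness is undefined. Returns
    ``(library, position, outcome)`` triples.
    """
    out = []
    for lib in design.libraries:
        window = design.window_nt(lib)
        lo, _ = design.window_residue_range(lib)
        for _, prow in design.library_positions(lib).iterrows():
            pos = int(prow.position)
            off = (pos - lo) * 3
            for outcome, codons in AA_TO_CODONS.items():
                variants = [c for c in codons if c != prow.wt_codon]
                if not variants:
                    continue
                if all(
                    _has_mmei(window[:off] + c + window[off + 3 :]) for c in variants
                ):
                    out.append((lib, pos, outcome))
    return out


def apply_exclusions(
    landscape: FitnessLandscape,
    design: LibraryDesign | None = None,
    min_count_t0: int = 10,
    counts: CountTimeSeries | None = None,
    mmei_cells: list[tuple[int, int, str]] | None = None,
    poor_coverage_cells: list[tuple[int, int, str]] | None = None,
) -> FitnessLandscape:
    """Drop MmeI-forced and poor-coverage cells from a landscape.

    MmeI cells come either from ``mmei_cells`` (explicit list of
    (library, position, outcome)) or are derived from the design. Poor
    coverage means an initial-time-point count below ``min_count_t0`` (when
    ``counts`` are supplied) or an explicit ``poor_coverage_cells`` list.
    A cell flagged both ways is excluded once, with reason ``mmei``.
    Surviving values are never altered — only membership changes.
    """
    if mmei_cells is None:
        mmei_cells = mmei_forced_cells(design) if design is not None else []
    mmei_set = set(mmei_cells)
    poor_set = set(poor_coverage_cells or [])
    if counts is not None:
        t0 = counts.timepoints[0]
        agg = counts.aggregate_outcomes()
        at_t0 = agg.counts[agg.counts.timepoint == t0]
        seen = {
            (int(r.library), int(r.position), r.outcome): r["count"]
            for _, r in at_t0.iterrows()
        }
        for _, row in landscape.table.iterrows():
            key = (int(row.library), int(row.position), row.outcome)
            if seen.get(key, 0) < min_count_t0:
                poor_set.add(key)

    table = landscape.table.copy()
    exclusions = list(landscape.exclusions)
    keys = list(zip(table.library.astype(int), table.position.astype(int), table.outcome))
    reasons = []
    for key in keys:
        if key in mmei_set:
            reasons.append("mmei")
        elif key in poor_set:
            reasons.append("low_coverage")
        else:
            reasons.append(None)
    for key, reason in zip(keys, reasons):
        if reason is not None:
            exclusions.append(
                {
                    "orthologue": landscape.orthologue,
                    "library": key[0],
                    "position": key[1],
                    "outcome": key[2],
                    "reason": reason,
                }
            )
    mask = np.array([r is not None for r in reasons])
    table.loc[mask, "s"] = np.nan
    table.loc[mask, "w"] = np.nan
    table.loc[mask, "flags"] = [
        (f + "," if f else "") + ("mmei_excluded" if r == "mmei" else "low_coverage")
        for f, r in zip(table.loc[mask, "flags"], np.array(reasons, dtype=object)[mask])
    ]
    return FitnessLandscape(
        table=table, stop_means=dict(landscape.stop_means), exclusions=exclusions
    )


def landscape_stats(landscape: FitnessLandscape, bins: int = 40) -> dict:
    """Summary of the distribution of fitness effects.

    Reports the deleterious (s < -0.75), detrimental (s < -0.5) and
    beneficial (s > 0) fractions, a histogram, and its local modes.
    """
    s = landscape.s_values()
    if s.size == 0:
        raise ValueError("empty landscape")
    hist, edges = np.histogram(s, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    modes = [
        float(centers[i])
        for i in range(len(hist))
        if hist[i] > 0
        and (i == 0 or hist[i] >= hist[i - 1])
        and (i == len(hist) - 1 or hist[i] > hist[i + 1])
    ]
    return {
        "n": int(s.size),
        "fraction_deleterious": float(np.mean(s < -0.75)),
        "fraction_detrimental": float(np.mean(s < -0.5)),
        "fraction_beneficial": float(np.mean(s > 0)),
        "mean": float(s.mean()),
        "histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
        "modes": modes,
    }


def design_accounting(
    n_orthologues: int = 3,
    n_libraries: int = 8,
    positions_per_library: int = 10,
    n_outcome_classes: int = 21,
    n_mmei_excluded: int = 79,
    poor_coverage: tuple = POOR_COVERAGE_MUTATIONS,
) -> dict:
    """Enumerate the full design and apply the exclusion accounting.

    Builds the complete cell grid (orthologues x libraries x positions x
    outcome classes), flags ``n_mmei_excluded`` deterministic cells as
    MmeI-forced (a synthetic stand-in: the specific cells are arbitrary,
    the count is what matters) plus the named poor-coverage mutations, and
    reports how many cells remain analysable.
    """
    from .alphabet import OUTCOME_CLASSES

    orthologues = [name for name, _, _, _ in poor_coverage]
    # keep the real orthologue names when the default poor-coverage set is used
    names = list(dict.fromkeys(orthologues))
    while len(names) < n_orthologues:
        names.append(f"ortho{len(names) + 1}")
    names = names[:n_orthologues]
    classes = list(OUTCOME_CLASSES[:n_outcome_classes])

    rows = []
    for name in names:
        for lib in range(1, n_libraries + 1):
            for wp in range(1, positions_per_library + 1):
                pos = (lib - 1) * positions_per_library + wp
                for outcome in classes:
                    rows.append((name, lib, pos, outcome))
    grid = pd.DataFrame(rows, columns=["orthologue", "library", "position", "outcome"])

    # Poor-coverage mutations are named by residue number in each construct's
    # own numbering; map them onto the grid by (orthologue, position mod the
    # grid's span, substituted residue) — the identity of the substitution is
    # what is excluded, one cell each.
    span = n_libraries * positions_per_library
    excluded = np.zeros(len(grid), dtype=bool)
    reason = np.array([""] * len(grid), dtype=object)
    for name, _wt, pos, sub in poor_coverage:
        grid_pos = (pos - 1) % span + 1
        hit = (
            (grid.orthologue == name)
            & (grid.position == grid_pos)
            & (grid.outcome == sub)
        )
        idx = np.flatnonzero(hit.to_numpy() & ~excluded)
        if idx.size:
            excluded[idx[0]] = True
            reason[idx[0]] = "low_coverage"

    # The MmeI-forced cells of the original libraries are not enumerated
    # anywhere; flag a deterministic synthetic set of the stated size (the
    # first eligible cells in grid order).
    free = np.flatnonzero(~excluded)
    mmei_idx = free[:n_mmei_excluded]
    excluded[mmei_idx] = True
    reason[mmei_idx] = "mmei"

    analysed = int((~excluded).sum())
    return {
        "total_cells": int(len(grid)),
        "mmei_excluded": int((reason == "mmei").sum()),
        "poor_coverage": int((reason == "low_coverage").sum()),
        "analysed": analysed,
    }
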