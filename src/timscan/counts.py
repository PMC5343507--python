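"""Per-variant count trajectories from a bulk growth competition.

Each library is an independent selection experiment: a pool of single-codon
variants plus the WT gene grows competitively, and deep sequencing samples
the pool at a series of time points (measured in WT doublings). Counts are
tracked per (library, position, amino-acid outcome class, time point);
reads that match the WT reference exactly are the common WT denominator of
every position in their library.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["library", "position", "outcome", "codon", "timepoint", "count"]
WT_COLUMNS = ["library", "timepoint", "count"]


@dataclasses.dataclass
class CountTimeSeries:
    """Variant and WT counts over the time points of a competition.

    Attributes
    ----------
    counts : pandas.DataFrame
        Columns ``library, position, outcome, codon, timepoint, count``.
        ``codon`` may be empty when counts were aggregated at the
        amino-acid level.
    wt_counts : pandas.DataFrame
        Columns ``library, timepoint, count`` — reads identical to the WT
        reference at the nucleotide level. They serve as the WT count for
        every position of the library.
    timepoints : tuple of float
        Sampling times in WT doublings, strictly increasing.
    truth : pandas.DataFrame or None
        For simulated data: per-variant true raw fitness ``w_true`` and true
        selection coefficient ``s_true`` (recovery tests read these).
    """

    counts: pd.DataFrame
    wt_counts: pd.DataFrame
    timepoints: tuple[float, ...]
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if len(self.timepoints) == 0:
            raise ValueError("at least one time point required")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if (self.counts["count"] < 0).any() or (self.wt_counts["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    # ---- accessors ------------------------------------------------------

    def variant_series(self, library: int, position: int, outcome: str) -> np.ndarray:
        """Counts of one variant over ``self.timepoints`` (0 where unobserved)."""
        sub = self.counts[
            (self.counts.library == library)
            & (self.counts.position == position)
            & (self.counts.outcome == outcome)
        ]
        agg = sub.groupby("timepoint")["count"].sum()
        return np.array([float(agg.get(t, 0.0)) for t in self.timepoints])

    def wt_series(self, library: int) -> np.ndarray:
        sub = self.wt_counts[self.wt_counts.library == library]
        agg = sub.groupby("timepoint")["count"].sum()
        return np.array([float(agg.get(t, 0.0)) for t in self.timepoints])

    def total_per_timepoint(self, library: int) -> np.ndarray:
        """Total sequenced molecules per time point (variants + WT)."""
        var = (
            self.counts[self.counts.library == library]
            .groupby("timepoint")["count"]
            .sum()
        )
        out = []
        for t in self.timepoints:
            wt = self.wt_series(library)[list(self.timepoints).index(t)]
            out.append(float(var.get(t, 0.0)) + wt)
        return np.array(out)

    def aggregate_outcomes(self) -> "CountTimeSeries":
        """Pool synonymous codons into their amino-acid outcome class."""
        agg = (
            self.counts.groupby(["library", "position", "outcome", "timepoint"])[
                "count"
            ]
            .sum()
            .reset_index()
        )
        agg["codon"] = ""
        return CountTimeSeries(
            counts=agg[COUNT_COLUMNS],
            wt_counts=self.wt_counts,
            timepoints=self.timepoints,
            truth=self.truth,
        )

    # ---- serialization --------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        wt = self.wt_counts.copy()
        wt["position"] = 0  # sentinel row: WT reference of the whole library
        wt["outcome"] = "WT"
        wt["codon"] = ""
        pd.concat([df, wt[COUNT_COLUMNS]], ignore_index=True).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTimeSeries":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        wt = df[df.outcome == "WT"][["library", "timepoint", "count"]].reset_index(
            drop=True
        )
        counts = df[df.outcome != "WT"].reset_index(drop=True)
        tps = tuple(sorted(set(df.timepoint.astype(float))))
        return cls(counts=counts[COUNT_COLUMNS], wt_counts=wt, timepoints=tps)
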