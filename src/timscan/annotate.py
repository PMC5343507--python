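"""Structural and evolutionary annotation of library positions.

Covers the metadata the comparative analyses stratify on: the TIM barrel's
four-fold symmetry index (grouping consecutive odd/even library pairs into
4 quadrants x 20 offsets), relative solvent accessibility from absolute
ASA via an empirical per-residue maximum scale, WT conservation and column
information content from a multiple sequence alignment, and WT-residue
hydrophobicity (Kyte-Doolittle by default).

Structural alignments, ASA and b-factors are consumed as tables computed
elsewhere; this module never derives them from coordinates.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AA20

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

GAP_CHARS = frozenset("-.")


def load_max_asa() -> dict[str, float]:
    """Empirical maximum ASA per residue (theoretical tripeptide scale)."""
    with resources.files("timscan.data").joinpath("max_asa.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df.residue, df.max_asa.astype(float)))


def fourfold_index(library: int, within_position: int) -> tuple[int, int]:
    """Map a (library, within-library position) slot to its four-fold cell.

    Libraries pair up as consecutive odd/even strands: quadrant =
    ceil(library / 2); the offset runs 1-10 through the odd library and
    11-20 through the even one. With 8 libraries of 10 positions this is a
    bijection onto 4 quadrants x 20 offsets.
    """
    if not 1 <= library <= 8:
        raise ValueError(f"library must be in 1..8, got {library}")
    if not 1 <= within_position <= 10:
        raise ValueError(f"within_position must be in 1..10, got {within_position}")
    quadrant = (library + 1) // 2
    offset = within_position if library % 2 == 1 else within_position + 10
    return quadrant, offset


def rsa_from_asa(
    asa: float,
    wt_residue: str,
    max_asa_table: dict[str, float] | None = None,
    cap: float | None = 1.0,
) -> float:
    """Relative solvent accessibility: ASA / residue maximum, capped at 1."""
    if asa < 0:
        raise ValueError("asa must be non-negative")
    table = max_asa_table if max_asa_table is not None else load_max_asa()
    if wt_residue not in table:
        raise KeyError(f"residue {wt_residue!r} not in max-ASA table")
    rsa = asa / table[wt_residue]
    if cap is not None:
        rsa = min(rsa, cap)
    return float(rsa)


def _nongap(column) -> list[str]:
    return [c.upper() for c in column if c not in GAP_CHARS and c.upper() not in GAP_CHARS]


def wt_conservation(msa_column, wt_residue: str) -> float:
    """Fraction of non-gap alignment rows carrying the WT residue."""
    residues = _nongap(msa_column)
    if not residues:
        raise ValueError("all-gap column: conservation undefined")
    return sum(1 for c in residues if c == wt_residue.upper()) / len(residues)


def information_content(msa_column, pseudocount: float = 0.0) -> float:
    """Shannon information content of a column in bits.

    IC = log2(20) - H(frequencies), with gaps excluded and ``pseudocount``
    added to each of the 20 amino-acid counts before normalization. A fully
    conserved column scores log2(20) ~ 4.32 bits; a uniform one scores 0.
    """
    residues = _nongap(msa_column)
    if not residues:
        raise ValueError("all-gap column: information content undefined")
    counts = np.array([sum(1 for c in residues if c == aa) for aa in AA20], dtype=float)
    counts += pseudocount
    freqs = counts / counts.sum()
    nz = freqs[freqs > 0]
    entropy = -float(np.sum(nz * np.log2(nz)))
    return float(np.log2(20.0) - entropy)


def column_frequencies(msa_column, pseudocount: float = 0.0) -> pd.Series:
    """Amino-acid frequency vector of a column (gaps excluded)."""
    residues = _nongap(msa_column)
    counts = np.array([sum(1 for c in residues if c == aa) for aa in AA20], dtype=float)
    counts += pseudocount
    total = counts.sum()
    if total == 0:
        raise ValueError("empty column after gap removal")
    return pd.Series(counts / total, index=list(AA20))


@dataclasses.dataclass
class AlignmentMap:
    """Position correspondences between two orthologues.

    ``pairs`` has columns ``pos_a, aa_a, pos_b, aa_b``; ``kind`` records how
    the map was built (structural, sequence, or fourfold). Maps are
    involutive: ``m.invert().invert()`` restores the original pairing.
    """

    pairs: pd.DataFrame
    kind: str = "structural"

    def __post_init__(self) -> None:
        req = {"pos_a", "aa_a", "pos_b", "aa_b"}
        if req - set(self.pairs.columns):
            raise ValueError(f"alignment map needs columns {sorted(req)}")
        if self.pairs.pos_a.duplicated().any() or self.pairs.pos_b.duplicated().any():
            raise ValueError("each position may appear at most once per map")
        if self.kind not in ("structural", "sequence", "fourfold"):
            raise ValueError(f"unknown map kind {self.kind!r}")

    def invert(self) -> "AlignmentMap":
        inv = self.pairs.rename(
            columns={"pos_a": "pos_b", "pos_b": "pos_a", "aa_a": "aa_b", "aa_b": "aa_a"}
        )[["pos_a", "aa_a", "pos_b", "aa_b"]]
        return AlignmentMap(pairs=inv.reset_index(drop=True), kind=self.kind)

    def to_tsv(self, path: str | Path) -> None:
        df = self.pairs.copy()
        df["kind"] = self.kind
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlignmentMap":
        df = pd.read_csv(path, sep="\t")
        kind = str(df.kind.iloc[0]) if "kind" in df.columns else "structural"
        return cls(pairs=df[["pos_a", "aa_a", "pos_b", "aa_b"]], kind=kind)


def annotate_positions(
    design_positions: pd.DataFrame,
    msa=None,
    position_to_column: dict[int, int] | None = None,
    structure_table: pd.DataFrame | None = None,
    hydrophobicity: dict[str, float] | None = None,
    max_asa_table: dict[str, float] | None = None,
    ic_pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Merge structural and evolutionary metadata into one per-position table.

    ``design_positions`` needs columns library, within_position, position,
    wt_aa. ``structure_table`` (optional) may carry element, layer,
    orientation, asa, b_factor per position; RSA is derived from ASA when
    present. ``msa`` plus ``position_to_column`` (1-based position to
    0-based alignment column) add WT conservation and information content.
    """
    hydro = hydrophobicity or KYTE_DOOLITTLE
    rows = []
    for _, prow in design_positions.iterrows():
        quadrant, offset = fourfold_index(int(prow.library), int(prow.within_position))
        rec = {
            "position": int(prow.position),
            "library": int(prow.library),
            "within_position": int(prow.within_position),
            "wt_aa": prow.wt_aa,
            "fourfold_quadrant": quadrant,
            "fourfold_offset": offset,
            "wt_hydrophobicity": hydro.get(prow.wt_aa, np.nan),
        }
        rows.append(rec)
    annot = pd.DataFrame(rows)
    if structure_table is not None:
        annot = annot.merge(structure_table, on="position", how="left")
        if "asa" in annot.columns:
            table = max_asa_table if max_asa_table is not None else load_max_asa()
            annot["rsa"] = [
                rsa_from_asa(a, aa, table) if pd.notna(a) else np.nan
                for a, aa in zip(annot.asa, annot.wt_aa)
            ]
    if msa is not None and position_to_column is not None:
        cons, ic = [], []
        for _, row in annot.iterrows():
            col_idx = position_to_column.get(int(row.position))
            if col_idx is None:
                cons.append(np.nan)
                ic.append(np.nan)
                continue
            column = [str(rec.seq[col_idx]) for rec in msa]
            cons.append(wt_conservation(column, row.wt_aa))
            ic.append(information_content(column, pseudocount=ic_pseudocount))
        annot["wt_conservation"] = cons
        annot["information_content"] = ic
    return annot
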