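"""Library designs for saturation-mutagenesis growth competitions.

A design describes one orthologue's mutagenesis scheme: a reference gene,
contiguous windows ("libraries") of mutagenized codons (10 per library in
the canonical layout, 8 libraries tiling the beta-barrel), the WT codon and
residue at each position, and the time-stamping barcodes used to multiplex
time points on one sequencing run.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA20, CODON_TO_AA, OUTCOME_CLASSES, translate_codon

_NONSTOP_CODONS = tuple(c for c, aa in CODON_TO_AA.items() if aa != "*")

#: MmeI recognition motif (TCCRAC) and its reverse complement, as plain strings.
_MMEI_FORWARD = ("TCCAAC", "TCCGAC")
_MMEI_REVERSE = ("GTTGGA", "GTCGGA")
_MMEI_ALL = _MMEI_FORWARD + _MMEI_REVERSE


def _has_mmei(seq: str) -> bool:
    return any(m in seq for m in _MMEI_ALL)


@dataclasses.dataclass
class LibraryDesign:
    """Mutagenesis scheme for one orthologue.

    Parameters
    ----------
    orthologue : str
        Name of the gene/orthologue.
    reference : str
        Full nucleotide sequence of the ORF (length divisible by 3).
    positions : pandas.DataFrame
        One row per mutagenized position with columns
        ``library`` (1-based), ``within_position`` (1-based index inside the
        library window), ``position`` (1-based residue number in the ORF),
        ``wt_codon`` and ``wt_aa``.
    barcode_map : dict
        Maps time point (in WT doublings) to its barcode sequence. May be
        empty for designs used without read emission.
    """

    orthologue: str
    reference: str
    positions: pd.DataFrame
    barcode_map: dict[float, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        if len(self.reference) % 3 != 0:
            raise ValueError("reference length must be a multiple of 3")
        req = {"library", "within_position", "position", "wt_codon", "wt_aa"}
        missing = req - set(self.positions.columns)
        if missing:
            raise ValueError(f"positions table missing columns: {sorted(missing)}")
        for _, row in self.positions.iterrows():
            start = (int(row.position) - 1) * 3
            codon = self.reference[start : start + 3]
            if codon != row.wt_codon:
                raise ValueError(
                    f"wt_codon {row.wt_codon} at position {row.position} does not "
                    f"match reference codon {codon}"
                )
            if translate_codon(row.wt_codon) != row.wt_aa:
                raise ValueError(f"wt_aa mismatch at position {row.position}")
        if len(self.barcode_map) != len(set(self.barcode_map.values())):
            raise ValueError("barcode collision: barcodes must be distinct")
        counts = self.positions.groupby("library").size()
        self._libraries = tuple(int(x) for x in sorted(counts.index))

    # ---- geometry -------------------------------------------------------

    @property
    def libraries(self) -> tuple[int, ...]:
        return self._libraries

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def barcode_length(self) -> int:
        if not self.barcode_map:
            return 0
        (bl,) = {len(b) for b in self.barcode_map.values()}
        return bl

    @property
    def barcode_to_time(self) -> dict[str, float]:
        return {b: t for t, b in self.barcode_map.items()}

    def library_positions(self, library: int) -> pd.DataFrame:
        sub = self.positions[self.positions.library == library]
        if sub.empty:
            raise KeyError(f"no such library: {library}")
        return sub.sort_values("within_position")

    def window_residue_range(self, library: int) -> tuple[int, int]:
        """First and last residue number (inclusive) of a library window."""
        sub = self.library_positions(library)
        return int(sub.position.min()), int(sub.position.max())

    def window_nt(self, library: int) -> str:
        """WT nucleotide sequence of the library's mutagenized window."""
        lo, hi = self.window_residue_range(library)
        return self.reference[(lo - 1) * 3 : hi * 3]

    def wt_aa_at(self, position: int) -> str:
        sub = self.positions[self.positions.position == position]
        if sub.empty:
            raise KeyError(f"position {position} not in design")
        return str(sub.wt_aa.iloc[0])

    def cells(self) -> pd.DataFrame:
        """All (library, position, outcome) cells — 21 outcome classes/position."""
        rows = []
        for _, row in self.positions.iterrows():
            for outcome in OUTCOME_CLASSES:
                rows.append(
                    (
                        self.orthologue,
                        int(row.library),
                        int(row.position),
                        row.wt_aa,
                        outcome,
                    )
                )
        return pd.DataFrame(
            rows, columns=["orthologue", "library", "position", "wt_aa", "outcome"]
        )

    # ---- serialization --------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        df = self.positions.copy()
        df.insert(0, "orthologue", self.orthologue)
        bc = ";".join(f"{t}={b}" for t, b in sorted(self.barcode_map.items()))
        df["barcodes"] = bc
        df.to_csv(path, sep="\t", index=False)

    def write_reference(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.reference), id=self.orthologue, description="")
        SeqIO.write([rec], str(path), "fasta")

    @classmethod
    def from_tsv(cls, design_path: str | Path, reference_path: str | Path) -> "LibraryDesign":
        df = pd.read_csv(design_path, sep="\t")
        rec = next(SeqIO.parse(str(reference_path), "fasta"))
        barcode_map: dict[float, str] = {}
        if "barcodes" in df.columns and isinstance(df.barcodes.iloc[0], str) and df.barcodes.iloc[0]:
            for item in df.barcodes.iloc[0].split(";"):
                t, b = item.split("=")
                barcode_map[float(t)] = b
        cols = ["library", "within_position", "position", "wt_codon", "wt_aa"]
        return cls(
            orthologue=str(df.orthologue.iloc[0]),
            reference=str(rec.seq),
            positions=df[cols].reset_index(drop=True),
            barcode_map=barcode_map,
        )


def random_design(
    n_libraries: int = 8,
    positions_per_library: int = 10,
    orthologue: str = "SYN",
    seed: int | np.random.Generator = 0,
    timepoints: tuple[float, ...] = (),
    barcode_length: int = 6,
) -> LibraryDesign:
    """Draw a synthetic design: contiguous library windows on a random ORF.

    WT codons are sampled from the 61 sense codons; windows are resampled
    until the WT reference is free of MmeI recognition sites on both strands
    (a site in the WT context would reject every read of that library).
    If ``timepoints`` are given, one distinct barcode per time point is drawn.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    codons: list[str] = []
    for _ in range(n_libraries):
        while True:
            window = list(rng.choice(_NONSTOP_CODONS, size=positions_per_library))
            joined = "".join(codons[-1:]) + "".join(window)  # guard the junction too
            if not _has_mmei(joined):
                codons.extend(window)
                break
    reference = "".join(codons)
    rows = []
    for i, codon in enumerate(codons):
        rows.append(
            {
                "library": i // positions_per_library + 1,
                "within_position": i % positions_per_library + 1,
                "position": i + 1,
                "wt_codon": codon,
                "wt_aa": translate_codon(codon),
            }
        )
    barcode_map: dict[float, str] = {}
    if timepoints:
        seen: set[str] = set()
        for t in timepoints:
            while True:
                bc = "".join(rng.choice(list("ACGT"), size=barcode_length))
                if bc not in seen and not _has_mmei(bc):
                    seen.add(bc)
                    barcode_map[float(t)] = bc
                    break
    return LibraryDesign(
        orthologue=orthologue,
        reference=reference,
        positions=pd.DataFrame(rows),
        barcode_map=barcode_map,
    )
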