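"""Read filtering and variant counting for barcoded competition sequencing.

Each read carries a time-stamping barcode followed by one library's
mutagenized window. Reads are accepted only if they clear four criteria,
evaluated in a fixed order so reports are reproducible:

1. quality  — every base at or above the Phred threshold (default Q >= 20),
2. barcode  — the leading bases match a known time-point barcode,
3. reference — the remainder matches exactly one library window either
   perfectly (WT) or with a single codon substitution,
4. mmei     — no MmeI recognition site (TCCRAC, either strand): the enzyme
   cuts such reads during barcode ligation, so their counts are unusable.

Accepted reads are tabulated per (library, position, outcome class, time
point) at both the codon and amino-acid level; exact-WT reads form the WT
denominator of their library.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alphabet import translate_codon
from .counts import COUNT_COLUMNS, CountTimeSeries
from .design import LibraryDesign

REJECTION_ORDER = ("quality", "barcode", "reference", "mmei")

_MMEI_RE = re.compile("TCC[AG]AC|GT[TC]GGA")
_VALID_RE = re.compile("^[ACGT]*$")


@dataclasses.dataclass
class ReadRecord:
    identifier: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")


@dataclasses.dataclass
class FilterReport:
    total: int = 0
    passed: int = 0
    rejected_by_reason: dict[str, int] = dataclasses.field(
        default_factory=lambda: {r: 0 for r in REJECTION_ORDER}
    )

    def record(self, reason: str | None) -> None:
        self.total += 1
        if reason is None:
            self.passed += 1
        else:
            self.rejected_by_reason[reason] += 1

    def check(self) -> None:
        if self.passed + sum(self.rejected_by_reason.values()) != self.total:
            raise AssertionError("filter report does not conserve reads")

    def to_json(self, path: str | Path) -> None:
        self.check()
        Path(path).write_text(
            json.dumps(
                {
                    "total": self.total,
                    "passed": self.passed,
                    "rejected_by_reason": self.rejected_by_reason,
                },
                indent=1,
            )
        )


def contains_mmei_site(sequence: str) -> bool:
    """True iff TCCRAC occurs on either strand of ``sequence``."""
    seq = sequence.upper()
    if not _VALID_RE.match(seq):
        raise ValueError("sequence must contain only A, C, G, T")
    return _MMEI_RE.search(seq) is not None


@dataclasses.dataclass
class Classification:
    """Outcome of matching a read against the design."""

    kind: str  # "wt" | "variant" | "ambiguous"
    library: int | None = None
    position: int | None = None
    codon: str | None = None
    outcome: str | None = None


def classify_read(read: ReadRecord, design: LibraryDesign) -> Classification:
    """Match a (quality/barcode-passing) read to a WT or single-codon variant.

    The post-barcode payload is compared against every library window at its
    fixed anchor; a read is a variant only if exactly one codon differs from
    WT (all other bases identical) in exactly one library. Anything else is
    ambiguous and rejected as a reference mismatch.
    """
    bl = design.barcode_length
    payload = read.sequence[bl:]
    hits: list[Classification] = []
    for lib in design.libraries:
        window = design.window_nt(lib)
        lo, hi = design.window_residue_range(lib)
        tail = design.reference[hi * 3 : hi * 3 + max(0, len(payload) - len(window))]
        ref = (window + tail)[: len(payload)]
        if len(ref) < len(payload):
            ref = ref + "A" * (len(payload) - len(ref))
        if payload == ref:
            hits.append(Classification(kind="wt", library=lib))
            continue
        diff = [i for i, (a, b) in enumerate(zip(payload, ref)) if a != b]
        codon_slots = {i // 3 for i in diff}
        if len(codon_slots) == 1:
            (slot,) = codon_slots
            if slot < hi - lo + 1:  # inside the mutagenized window
                codon = payload[slot * 3 : slot * 3 + 3]
                if len(codon) == 3:
                    hits.append(
                        Classification(
                            kind="variant",
                            library=lib,
                            position=lo + slot,
                            codon=codon,
                            outcome=translate_codon(codon),
                        )
                    )
    if len(hits) == 1:
        return hits[0]
    return Classification(kind="ambiguous")


def filter_read(
    read: ReadRecord, design: LibraryDesign, min_phred: int = 20
) -> tuple[str | None, Classification | None, float | None]:
    """Apply the four acceptance criteria in their fixed order.

    Returns ``(rejection_reason, classification, time)``; reason is None for
    accepted reads. The MmeI scan runs on the post-barcode payload (the
    mutagenized window in its reference context).
    """
    if any(q < min_phred for q in read.qualities):
        return "quality", None, None
    bl = design.barcode_length
    if len(read.sequence) < bl:
        return "barcode", None, None
    time = design.barcode_to_time.get(read.sequence[:bl])
    if time is None:
        return "barcode", None, None
    cls = classify_read(read, design)
    if cls.kind == "ambiguous":
        return "reference", None, None
    if contains_mmei_site(read.sequence[bl:]):
        return "mmei", None, None
    return None, cls, time


def tabulate(
    classified: list[tuple[float, Classification]],
    timepoints: tuple[float, ...],
    report: FilterReport | None = None,
    pool_synonymous_wt: bool = False,
) -> CountTimeSeries:
    """Aggregate accepted classified reads into a count table.

    Synonymous codons pool into one amino-acid outcome class while
    codon-level counts are retained. Exact-WT reads go to the WT
    denominator; synonymous-WT codon *variants* stay in the WT amino acid's
    outcome class unless ``pool_synonymous_wt`` also adds them to the
    denominator.
    """
    counts: dict[tuple, int] = {}
    wt: dict[tuple, int] = {}
    for time, cls in classified:
        if cls.kind == "wt":
            key = (cls.library, time)
            wt[key] = wt.get(key, 0) + 1
        elif cls.kind == "variant":
            key = (cls.library, cls.position, cls.outcome, cls.codon, time)
            counts[key] = counts.get(key, 0) + 1
        else:
            raise RuntimeError("ambiguous read reached tabulation; filter first")
    rows = [
        {
            "library": k[0],
            "position": k[1],
            "outcome": k[2],
            "codon": k[3],
            "timepoint": k[4],
            "count": v,
        }
        for k, v in counts.items()
    ]
    wt_rows = [{"library": k[0], "timepoint": k[1], "count": v} for k, v in wt.items()]
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    wt_df = pd.DataFrame(wt_rows, columns=["library", "timepoint", "count"])
    if pool_synonymous_wt:
        raise NotImplementedError(
            "pooling synonymous-WT variants into the denominator requires the "
            "design; use process_reads(pool_synonymous_wt=True)"
        )
    if report is not None:
        report.check()
    return CountTimeSeries(counts=df, wt_counts=wt_df, timepoints=timepoints)


def process_reads(
    reads,
    design: LibraryDesign,
    min_phred: int = 20,
    pool_synonymous_wt: bool = False,
) -> tuple[CountTimeSeries, FilterReport]:
    """Filter, classify and tabulate an iterable of reads.

    ``reads`` yields :class:`ReadRecord` or Biopython ``SeqRecord`` objects.
    This module is fully deterministic: the same input always produces the
    same table.
    """
    report = FilterReport()
    accepted: list[tuple[float, Classification]] = []
    for rec in reads:
        if not isinstance(rec, ReadRecord):
            rec = ReadRecord(
                identifier=rec.id,
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
        reason, cls, time = filter_read(rec, design, min_phred=min_phred)
        report.record(reason)
        if reason is None:
            accepted.append((time, cls))
    timepoints = tuple(sorted(design.barcode_map))
    cts = tabulate(accepted, timepoints, report=report)
    if pool_synonymous_wt:
        syn = cts.counts.merge(
            design.positions[["position", "wt_aa"]], on="position", how="left"
        )
        mask = syn.outcome == syn.wt_aa
        extra = (
            syn[mask]
            .groupby(["library", "timepoint"])["count"]
            .sum()
            .reset_index()
        )
        wt = (
            pd.concat([cts.wt_counts, extra], ignore_index=True)
            .groupby(["library", "timepoint"])["count"]
            .sum()
            .reset_index()
        )
        cts = CountTimeSeries(
            counts=cts.counts[~mask.to_numpy()].reset_index(drop=True),
            wt_counts=wt,
            timepoints=cts.timepoints,
        )
    report.check()
    return cts, report


def process_fastq(
    paths,
    design: LibraryDesign,
    min_phred: int = 20,
    pool_synonymous_wt: bool = False,
) -> tuple[CountTimeSeries, FilterReport]:
    """Run :func:`process_reads` over FASTQ files (plain or gzipped)."""
    if isinstance(paths, (str, Path)):
        paths = [paths]

    def _iter():
        for p in paths:
            p = Path(p)
            if p.suffix == ".gz":
                with gzip.open(p, "rt") as fh:
                    yield from SeqIO.parse(fh, "fastq")
            else:
                yield from SeqIO.parse(str(p), "fastq")

    return process_reads(
        _iter(), design, min_phred=min_phred, pool_synonymous_wt=pool_synonymous_wt
    )
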