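"""Synthetic inputs for the pipeline: competitions, reads, trios, MSAs.

The generator is the test bed for every downstream stage. It emulates a
bulk growth competition: each library's variant pool grows exponentially,
a variant with raw fitness w changing its abundance relative to WT as
2**(w * t) with t in WT doublings, and sequencing draws a finite number of
reads per time point (multinomially by default). True fitness values are
recorded so estimators can be scored against the truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA20, AA_TO_CODONS, OUTCOME_CLASSES, STOP
from .counts import COUNT_COLUMNS, CountTimeSeries
from .design import LibraryDesign, _has_mmei, random_design
from .fitness import LANDSCAPE_COLUMNS, FitnessLandscape

DEFAULT_TIMEPOINTS = (0.0, 0.57, 1.14, 1.71, 2.29, 2.86, 3.43, 4.0)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclasses.dataclass
class SimulationConfig:
    """Settings of one simulated growth competition.

    ``true_s`` maps (position, outcome_class) to the true selection
    coefficient; when omitted a bimodal distribution of fitness effects is
    drawn (mostly strongly deleterious plus a near-neutral mode with a
    beneficial tail), with stop outcomes at s = -1 and the synonymous WT
    class at s = 0. ``stop_scale`` is |mean stop raw fitness| per doubling,
    i.e. the factor converting s to raw fitness w = s * stop_scale; the
    default 1.0 makes stops fully lethal and w numerically equal to s.
    ``wt_copies`` is the initial abundance of the WT gene relative to a
    single variant (cassette ligation leaves WT over-represented).
    """

    n_libraries: int = 1
    positions_per_library: int = 10
    depth_per_timepoint: float = 1e5
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    true_s: dict[tuple[int, str], float] | None = None
    seed: int = 0
    noise_model: str = "multinomial"  # multinomial | poisson | none
    stop_scale: float = 1.0
    wt_copies: float = 10.0
    design: LibraryDesign | None = None

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        if len(tp) == 0:
            raise ConfigurationError("timepoints must be non-empty")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigurationError("timepoints must be strictly increasing")
        self.timepoints = tp
        if self.depth_per_timepoint <= 0:
            raise ConfigurationError("depth_per_timepoint must be positive")
        if self.noise_model not in ("multinomial", "poisson", "none"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if self.stop_scale <= 0:
            raise ConfigurationError("stop_scale must be positive")


def default_true_s(
    design: LibraryDesign,
    rng: np.random.Generator,
    deleterious_fraction: float = 0.55,
    beneficial_fraction: float = 0.10,
    position_heterogeneity: float = 0.5,
) -> dict[tuple[int, str], float]:
    """Bimodal DFE: a lethal-side mode near -0.93 and a WT-like mode near 0.

    Stop outcomes are pinned at -1, the synonymous WT class at 0. The
    deleterious mode is tight enough that most of its mass sits below
    s = -0.75; the remainder splits between near-neutral and a mildly
    beneficial tail. Mutational tolerance varies between positions (buried
    positions tolerate almost nothing, surface loops most things): each
    position's deleterious probability is Beta-distributed around the
    global ``deleterious_fraction`` with spread ``position_heterogeneity``
    in (0, 1); 0 recovers a homogeneous landscape in the limit.
    """
    true_s: dict[tuple[int, str], float] = {}
    h = max(position_heterogeneity, 1e-6)
    conc = (1.0 - h) / h  # Beta concentration: large = homogeneous
    for _, row in design.positions.iterrows():
        pos = int(row.position)
        p_del = rng.beta(
            deleterious_fraction * (conc + 2), (1 - deleterious_fraction) * (conc + 2)
        )
        for outcome in OUTCOME_CLASSES:
            if outcome == STOP:
                s = -1.0
            elif outcome == row.wt_aa:
                s = 0.0
            else:
                u = rng.random()
                if u < p_del:
                    s = rng.normal(-0.93, 0.06)
                elif u < p_del + beneficial_fraction * (1 - p_del) / (1 - deleterious_fraction + 1e-9):
                    s = abs(rng.normal(0.12, 0.10))
                else:
                    s = rng.normal(0.0, 0.10)
                s = float(np.clip(s, -1.2, 0.9))
            true_s[(pos, outcome)] = float(s)
    return true_s


def _variant_codons(design: LibraryDesign) -> pd.DataFrame:
    """Pick one representative codon per (position, outcome) cell.

    Prefers a codon that does not create an MmeI site when substituted into
    the WT window (so clean simulations survive read filtering); cells whose
    every codon creates a site keep the first codon and are marked forced.
    The synonymous WT class is skipped at positions where the WT amino acid
    has a single codon (no synonymous variant exists).
    """
    rows = []
    for lib in design.libraries:
        window = design.window_nt(lib)
        lo, _ = design.window_residue_range(lib)
        for _, prow in design.library_positions(lib).iterrows():
            pos = int(prow.position)
            off = (pos - lo) * 3
            for outcome in OUTCOME_CLASSES:
                codons = [c for c in AA_TO_CODONS[outcome] if c != prow.wt_codon]
                if not codons:
                    continue
                clean = [
                    c
                    for c in codons
                    if not _has_mmei(window[:off] + c + window[off + 3 :])
                ]
                codon = clean[0] if clean else codons[0]
                rows.append(
                    {
                        "library": lib,
                        "position": pos,
                        "outcome": outcome,
                        "codon": codon,
                        "mmei_forced": not clean,
                    }
                )
    return pd.DataFrame(rows)


def simulate_growth_counts(config: SimulationConfig) -> CountTimeSeries:
    """Simulate per-variant counts across the competition's time points.

    Expected relative abundance of variant i at time t is proportional to
    its initial abundance times 2**(w_i * t), with w_i = s_i * stop_scale
    and WT at w = 0, so the expected log2 mutant/WT ratio is linear in t
    with slope w_i. Counts are drawn per library and time point from the
    configured noise model; ``noise_model="none"`` returns the exact
    expected (fractional) counts.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    if design is None:
        design = random_design(
            n_libraries=config.n_libraries,
            positions_per_library=config.positions_per_library,
            seed=rng,
            timepoints=config.timepoints,
        )
    true_s = config.true_s
    if true_s is None:
        true_s = default_true_s(design, rng)

    codons = _variant_codons(design)
    count_rows = []
    wt_rows = []
    truth_rows = []
    t = np.asarray(config.timepoints)
    for lib in design.libraries:
        sub = codons[codons.library == lib].reset_index(drop=True)
        s_vec = np.array(
            [true_s.get((int(r.position), r.outcome), 0.0) for _, r in sub.iterrows()]
        )
        w_vec = s_vec * config.stop_scale
        init = np.concatenate([np.ones(len(sub)), [config.wt_copies]])
        w_all = np.concatenate([w_vec, [0.0]])
        for ti, time in enumerate(t):
            weights = init * np.exp2(w_all * time)
            probs = weights / weights.sum()
            if config.noise_model == "multinomial":
                drawn = rng.multinomial(int(config.depth_per_timepoint), probs)
            elif config.noise_model == "poisson":
                drawn = rng.poisson(config.depth_per_timepoint * probs)
            else:
                drawn = config.depth_per_timepoint * probs
            for i, row in sub.iterrows():
                count_rows.append(
                    (lib, int(row.position), row.outcome, row.codon, time, drawn[i])
                )
            wt_rows.append((lib, time, drawn[-1]))
        for i, row in sub.iterrows():
            truth_rows.append(
                (
                    lib,
                    int(row.position),
                    row.outcome,
                    float(w_vec[i]),
                    float(s_vec[i]),
                )
            )
    counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    wt = pd.DataFrame(wt_rows, columns=["library", "timepoint", "count"])
    truth = pd.DataFrame(
        truth_rows, columns=["library", "position", "outcome", "w_true", "s_true"]
    )
    cts = CountTimeSeries(
        counts=counts, wt_counts=wt, timepoints=config.timepoints, truth=truth
    )
    cts.design = design  # noqa: B010 — carried for read emission / estimation
    return cts


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------


def emit_reads(
    counts: CountTimeSeries,
    design: LibraryDesign,
    barcodes: dict[float, str] | None = None,
    read_length: int = 36,
    quality: int = 30,
    corruption: float | dict[str, float] = 0.0,
    seed: int = 0,
) -> list[SeqRecord]:
    """Emit one sequencing read per counted molecule.

    Reads are barcode + library window (+ downstream reference context up to
    ``read_length``). ``corruption`` injects three independent Bernoulli
    failure channels — ``quality`` (one base dropped to Q2), ``barcode``
    (replaced by an unknown barcode), ``reference`` (two extra codon
    changes) — either as one total fraction split evenly or as a dict per
    channel. WT molecules yield exact reference reads.
    """
    rng = np.random.default_rng(seed)
    barcodes = barcodes or design.barcode_map
    if not barcodes:
        raise ValueError("no barcode map supplied")
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("barcode collision: barcodes must be distinct")
    (bl,) = {len(b) for b in barcodes.values()}
    if isinstance(corruption, dict):
        channels = {k: float(corruption.get(k, 0.0)) for k in ("quality", "barcode", "reference")}
    else:
        channels = {k: float(corruption) / 3.0 for k in ("quality", "barcode", "reference")}
    known = set(barcodes.values())

    def window_payload(lib: int, pos: int | None, codon: str | None) -> str:
        lo, hi = design.window_residue_range(lib)
        window = design.window_nt(lib)
        if pos is not None:
            off = (pos - lo) * 3
            window = window[:off] + codon + window[off + 3 :]
        tail_needed = read_length - bl - len(window)
        if tail_needed < 0:
            raise ValueError("read_length shorter than barcode + window")
        tail = design.reference[hi * 3 : hi * 3 + tail_needed]
        if len(tail) < tail_needed:
            tail = tail + "A" * (tail_needed - len(tail))
        return window + tail

    records: list[SeqRecord] = []
    serial = 0

    def emit(lib: int, time: float, n: int, pos: int | None, codon: str | None) -> None:
        nonlocal serial
        if n <= 0:
            return
        if abs(n - round(n)) > 1e-9:
            raise ValueError("read emission needs integer counts (use a noise model)")
        payload = window_payload(lib, pos, codon)
        bc = barcodes[time]
        for _ in range(int(round(n))):
            seq = bc + payload
            qual = [quality] * read_length
            if rng.random() < channels["barcode"]:
                while True:
                    bad = "".join(rng.choice(list("ACGT"), size=bl))
                    if bad not in known:
                        break
                seq = bad + payload
            if rng.random() < channels["reference"]:
                lo, hi = design.window_residue_range(lib)
                n_codons = hi - lo + 1
                slots = rng.choice(n_codons, size=2, replace=False)
                chars = list(seq)
                for slot in slots:
                    start = bl + slot * 3
                    wt_codon = seq[start : start + 3]
                    while True:
                        new = "".join(rng.choice(list("ACGT"), size=3))
                        if new != wt_codon:
                            break
                    chars[start : start + 3] = new
                seq = "".join(chars)
            if rng.random() < channels["quality"]:
                qual = list(qual)
                qual[int(rng.integers(read_length))] = 2
            rec = SeqRecord(Seq(seq), id=f"read{serial}", description="")
            rec.letter_annotations["phred_quality"] = qual
            records.append(rec)
            serial += 1

    for _, row in counts.counts.iterrows():
        emit(
            int(row.library),
            float(row.timepoint),
            row["count"],
            int(row.position),
            row.codon,
        )
    for _, row in counts.wt_counts.iterrows():
        emit(int(row.library), float(row.timepoint), row["count"], None, None)
    return records


def write_fastq(records: list[SeqRecord], path) -> None:
    from Bio import SeqIO

    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# landscape trios
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LandscapeTrioConfig:
    """Three orthologue landscapes with a tunable shared signal.

    Per aligned position each orthologue's 20-value amino-acid profile is
    sqrt(rho) * shared + sqrt(1 - rho) * independent, both standard normal,
    so the expected cross-orthologue profile correlation equals ``rho``.
    Profiles are then placed on a realistic selection-coefficient scale
    (location + scale) which leaves correlations unchanged.
    """

    n_positions: int = 80
    rho: float = 0.5
    wt_policy: str = "identical"  # identical | sampled
    seed: int = 0
    positions_per_library: int = 10
    loc: float = -0.4
    scale: float = 0.35
    orthologues: tuple[str, str, str] = ("orthoA", "orthoB", "orthoC")

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigurationError("rho must be in [0, 1]")
        if self.n_positions < 2:
            raise ConfigurationError("n_positions must be >= 2")
        if self.wt_policy not in ("identical", "sampled"):
            raise ConfigurationError(f"unknown wt_policy {self.wt_policy!r}")


def simulate_landscape_trio(config: LandscapeTrioConfig):
    """Generate three correlated landscapes plus their alignment maps.

    Returns ``(landscapes, maps)`` where ``landscapes`` maps orthologue name
    to a :class:`FitnessLandscape` over the 20 amino-acid outcome classes
    and ``maps`` maps orthologue-name pairs to identity
    :class:`~timscan.annotate.AlignmentMap` objects (every aligned position
    pairs with itself).
    """
    from .annotate import AlignmentMap

    rng = np.random.default_rng(config.seed)
    n = config.n_positions
    shared = rng.standard_normal((n, 20))
    aa = np.array(AA20)
    wt_shared = rng.choice(20, size=n)
    landscapes: dict[str, FitnessLandscape] = {}
    wt_res: dict[str, np.ndarray] = {}
    for name in config.orthologues:
        indep = rng.standard_normal((n, 20))
        z = np.sqrt(config.rho) * shared + np.sqrt(1.0 - config.rho) * indep
        values = config.loc + config.scale * z
        if config.wt_policy == "identical":
            wt_idx = wt_shared
        else:
            wt_idx = rng.choice(20, size=n)
        wt_res[name] = aa[wt_idx]
        rows = []
        for p in range(n):
            lib = p // config.positions_per_library + 1
            for j, outcome in enumerate(AA20):
                rows.append(
                    {
                        "orthologue": name,
                        "library": lib,
                        "position": p + 1,
                        "wt_aa": aa[wt_idx[p]],
                        "outcome": outcome,
                        "w": values[p, j],
                        "s": values[p, j],
                        "flags": "",
                    }
                )
        landscapes[name] = FitnessLandscape(
            table=pd.DataFrame(rows, columns=LANDSCAPE_COLUMNS)
        )
    maps = {}
    names = config.orthologues
    for a in range(3):
        for b in range(a + 1, 3):
            na, nb = names[a], names[b]
            pairs = pd.DataFrame(
                {
                    "pos_a": np.arange(1, n + 1),
                    "aa_a": wt_res[na],
                    "pos_b": np.arange(1, n + 1),
                    "aa_b": wt_res[nb],
                }
            )
            maps[(na, nb)] = AlignmentMap(pairs=pairs, kind="structural")
    return landscapes, maps


# ---------------------------------------------------------------------------
# MSAs
# ---------------------------------------------------------------------------


def simulate_msa(
    column_profiles, n_sequences: int, seed: int = 0
) -> MultipleSeqAlignment:
    """Draw an alignment with independent columns from given profiles.

    ``column_profiles`` is an (L, 20) array or DataFrame (columns ordered as
    :data:`~timscan.alphabet.AA20`); each row must sum to 1.
    """
    if isinstance(column_profiles, pd.DataFrame):
        profiles = column_profiles[list(AA20)].to_numpy(dtype=float)
    else:
        profiles = np.asarray(column_profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != 20:
        raise ValueError("column_profiles must be (L, 20)")
    sums = profiles.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        bad = np.flatnonzero(~np.isclose(sums, 1.0, atol=1e-8))
        raise ValueError(f"column profiles not normalized at columns {bad.tolist()}")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA20))
    cols = [aa[rng.choice(20, size=n_sequences, p=p / p.sum())] for p in profiles]
    matrix = np.stack(cols, axis=1)
    records = [
        SeqRecord(Seq("".join(row)), id=f"seq{i}", description="")
        for i, row in enumerate(matrix)
    ]
    return MultipleSeqAlignment(records)
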