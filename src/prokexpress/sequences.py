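"""Gene sequences, codon classes and synthetic fixtures.

A :class:`GeneSequence` is the static input to a simulation: a DNA coding
sequence (length a multiple of 3), a translation-speed class or explicit rate
per codon, the methionine (ATG) codon positions used by pulse-labelling
experiments, and optional per-nucleotide site annotations (sequence-specific
long pauses or arrests with a triggering probability and mean duration).

Bundled defaults live in ``data/``: an approximate E. coli codon-usage table
(for random genes) and a codon→class table mapping each codon to one of the
three activation-rate classes A/B/C.  Both are plain TSV and meant to be
edited or replaced by the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "SiteAnnotation",
    "GeneSequence",
    "load_codon_classes",
    "load_codon_frequencies",
    "load_fasta",
    "generate_random_gene",
    "make_lacz_fixture",
    "annotate_site",
    "STOP_CODONS",
    "LACZ_LENGTH_CODONS",
    "LACZ_METHIONINE_CODONS",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
_VALID_CLASSES = frozenset({"A", "B", "C", "stop"})

#: Codon length of the LacZ-like fixture (3072 nt).
LACZ_LENGTH_CODONS = 1024

#: Fixed, unevenly spread methionine codon indices (1-based) of the LacZ-like
#: fixture; 23 positions, shared by all three variants, none inside the
#: slow-codon window replaced by the insert variants.
LACZ_METHIONINE_CODONS = (
    1, 8, 15, 42, 77, 96, 151, 188, 230, 269, 311, 338, 367, 404,
    441, 470, 589, 621, 700, 779, 844, 921, 1003,
)

_LACZ_INSERT_START = 513  # first codon replaced by the slow stretch
_LACZ_INSERT_CODON = "GAG"


@dataclass(frozen=True)
class SiteAnnotation:
    """A sequence-specific pause or arrest site on the DNA template.

    On each RNAp arrival at ``position`` the event triggers with
    ``probability``; a triggered RNAp halts with memoryless mean dwell
    ``mean_duration_s``.  Long-pause and arrest sites differ in that neither
    is released by collisions, but they are logged as distinct event types.
    """

    position: int
    kind: str  # "long_pause" | "arrest"
    probability: float
    mean_duration_s: float

    def __post_init__(self):
        if self.kind not in ("long_pause", "arrest"):
            raise ValueError(f"unknown site kind: {self.kind!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"site probability outside [0, 1]: {self.probability}")
        if self.mean_duration_s <= 0:
            raise ValueError(f"site mean duration must be positive: {self.mean_duration_s}")


def _data_path(name: str) -> Path:
    return Path(resources.files("prokexpress").joinpath("data", name))


def _read_tsv(path) -> list[tuple[str, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed row in {path}: {line!r}")
            rows.append((parts[0].strip().upper(), parts[1].strip()))
    return rows


def load_codon_classes(path=None) -> dict[str, Union[str, float]]:
    """Load a codon→class table (TSV: codon, class A|B|C|stop or a rate in /s).

    The table must cover all 64 codons.  A numeric second column gives that
    codon an explicit activation rate instead of a class.
    """
    rows = _read_tsv(path or _data_path("codon_classes.tsv"))
    table: dict[str, Union[str, float]] = {}
    for codon, value in rows:
        if codon in table and codon != "CODON":
            raise ValueError(f"duplicate codon in class table: {codon}")
        if codon == "CODON":  # header
            continue
        if value.upper() in ("A", "B", "C"):
            table[codon] = value.upper()
        elif value.lower() == "stop":
            table[codon] = "stop"
        else:
            try:
                table[codon] = float(value)
            except ValueError:
                raise ValueError(
                    f"codon {codon}: class must be A, B, C, stop or a rate, got {value!r}"
                ) from None
    missing = _all_codons() - set(table)
    if missing:
        raise ValueError(f"codon class table does not cover all 64 codons; missing {sorted(missing)}")
    return table


def load_codon_frequencies(path=None) -> dict[str, float]:
    """Load and renormalise a sense-codon frequency table (TSV: codon, weight)."""
    rows = _read_tsv(path or _data_path("codon_frequencies.tsv"))
    freqs = {}
    for codon, value in rows:
        if codon == "CODON":
            continue
        freqs[codon] = float(value)
    expected = _all_codons() - set(STOP_CODONS)
    if set(freqs) != expected:
        raise ValueError("frequency table must cover exactly the 61 sense codons")
    total = sum(freqs.values())
    if total <= 0:
        raise ValueError("frequency table has non-positive total weight")
    return {c: v / total for c, v in freqs.items()}


def _all_codons() -> set[str]:
    bases = "TCAG"
    return {a + b + c for a in bases for b in bases for c in bases}


@dataclass
class GeneSequence:
    """A coding sequence plus everything the simulator needs to translate it.

    Codon ``i`` (1-based) spans nucleotides ``3i-2 .. 3i``; nucleotide ``n``
    belongs to codon ``ceil(n/3)``.
    """

    nucleotides: str
    classes: dict[str, Union[str, float]] = field(repr=False, default=None)
    annotations: dict[int, SiteAnnotation] = field(default_factory=dict)
    name: str = "gene"

    def __post_init__(self):
        seq = self.nucleotides.upper()
        if len(seq) % 3 != 0:
            raise ValueError(
                f"sequence length {len(seq)} is not a multiple of 3"
            )
        for i, base in enumerate(seq, start=1):
            if base not in "ACGT":
                raise ValueError(f"non-ACGT character {base!r} at nucleotide {i}")
        self.nucleotides = seq
        if self.classes is None:
            self.classes = load_codon_classes()
        self.codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        for j, codon in enumerate(self.codons[:-1], start=1):
            if self.classes.get(codon) == "stop":
                # Permitted biologically only as the final codon; internal
                # stops would be read through by the model, so flag them.
                raise ValueError(f"internal stop codon {codon} at codon {j}")

    # ------------------------------------------------------------ geometry
    @property
    def length(self) -> int:
        """Length in nucleotides."""
        return len(self.nucleotides)

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    def codon(self, i: int) -> str:
        """Codon ``i`` (1-based)."""
        return self.codons[i - 1]

    @staticmethod
    def codon_of_nucleotide(n: int) -> int:
        return math.ceil(n / 3)

    @property
    def methionine_positions(self) -> tuple[int, ...]:
        """1-based codon indices of every ATG codon."""
        return tuple(i for i, c in enumerate(self.codons, start=1) if c == "ATG")

    # ------------------------------------------------------------ rates
    def activation_rates(self, params) -> np.ndarray:
        """Per-codon activation rates (1/s) under ``params`` (TranslationParameters).

        Explicit per-codon rates (``params.specific_codon_rates`` or a numeric
        entry in the class table) win over class rates.  The final stop codon
        gets 0 here — termination uses the completion rate instead.
        """
        class_rates = {"A": params.k_transA, "B": params.k_transB, "C": params.k_transC}
        rates = np.zeros(self.n_codons)
        for j, codon in enumerate(self.codons):
            if j == self.n_codons - 1 and self.classes.get(codon) == "stop":
                continue
            if codon in params.specific_codon_rates:
                rates[j] = params.specific_codon_rates[codon]
                continue
            cls = self.classes.get(codon)
            if isinstance(cls, float):
                rates[j] = cls
            elif cls in class_rates:
                rates[j] = class_rates[cls]
            else:
                raise ValueError(f"codon {codon} (index {j + 1}) has no resolvable rate")
        return rates


def load_fasta(path, classes: Optional[Mapping] = None) -> GeneSequence:
    """Read the first record of a FASTA file as a :class:`GeneSequence`."""
    records = SeqIO.parse(str(path), "fasta")
    try:
        record = next(records)
    except StopIteration:
        raise ValueError(f"no FASTA records in {path}") from None
    return GeneSequence(str(record.seq), classes=dict(classes) if classes else None,
                        name=record.id or "gene")


def generate_random_gene(
    length_codons: int,
    codon_frequency_table: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    classes: Optional[Mapping] = None,
    name: str = "random_gene",
) -> GeneSequence:
    """Random gene with i.i.d. sense codons drawn from a usage table.

    ``length_codons`` includes the final codon, which is forced to a stop
    (TAA).  The frequency table must sum to 1 over the 61 sense codons
    (within 1e-6); the bundled E. coli usage table is used when omitted.
    """
    if length_codons < 2:
        raise ValueError("a gene needs at least 2 codons (one sense + stop)")
    table = dict(codon_frequency_table) if codon_frequency_table else load_codon_frequencies()
    if set(table) != _all_codons() - set(STOP_CODONS):
        raise ValueError("frequency table must cover exactly the 61 sense codons")
    total = sum(table.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"codon frequencies must sum to 1 (got {total})")
    if any(v < 0 for v in table.values()):
        raise ValueError("codon frequencies must be non-negative")
    rng = np.random.default_rng(seed)
    codons = sorted(table)  # fixed order for reproducibility
    probs = np.array([table[c] for c in codons])
    probs = probs / probs.sum()
    draws = rng.choice(len(codons), size=length_codons - 1, p=probs)
    seq = "".join(codons[i] for i in draws) + "TAA"
    return GeneSequence(seq, classes=dict(classes) if classes else None, name=name)


def make_lacz_fixture(variant: str = "wt", seed: int = 0) -> GeneSequence:
    """Synthetic LacZ-like strand: 3072 nt, 23 unevenly spread methionines.

    This is a structural stand-in for the lacZ coding sequence and its
    engineered slow-codon mutants, not the real sequence: codons are drawn
    from the bundled usage table, ATG is placed at 23 fixed uneven positions,
    and the ``insert24`` / ``insert48`` variants replace a fixed mid-gene
    window of 24 or 48 codons with the slow (class C) codon GAG, emulating
    constructs whose slow stretch doubles between the two mutants.  All three
    variants share the methionine positions and differ only inside the
    replaced window.
    """
    if variant not in ("wt", "insert24", "insert48"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)
    table = load_codon_frequencies()
    # Exclude ATG from the background draw so the methionine count is exactly
    # the 23 placed positions.
    background = {c: v for c, v in table.items() if c != "ATG"}
    codon_list = sorted(background)
    probs = np.array([background[c] for c in codon_list])
    probs = probs / probs.sum()
    draws = rng.choice(len(codon_list), size=LACZ_LENGTH_CODONS - 1, p=probs)
    codons = [codon_list[i] for i in draws]
    for pos in LACZ_METHIONINE_CODONS:
        codons[pos - 1] = "ATG"
    if variant != "wt":
        n_slow = 24 if variant == "insert24" else 48
        for j in range(_LACZ_INSERT_START - 1, _LACZ_INSERT_START - 1 + n_slow):
            codons[j] = _LACZ_INSERT_CODON
    seq = "".join(codons) + "TAA"
    return GeneSequence(seq, name=f"lacZ_like_{variant}")


def annotate_site(
    sequence: GeneSequence,
    position: int,
    kind: str,
    probability: float,
    mean_duration_s: float,
) -> GeneSequence:
    """Attach a pause/arrest site annotation at a 1-based nucleotide position."""
    if not 1 <= position <= sequence.length:
        raise ValueError(
            f"site position {position} outside template [1, {sequence.length}]"
        )
    sequence.annotations[position] = SiteAnnotation(position, kind, probability, mean_duration_s)
    return sequence


def load_site_annotations(path) -> list[SiteAnnotation]:
    """Read site annotations from TSV: position, kind, probability, mean_duration_s."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("position"):
                continue
            pos, kind, prob, dur = line.split("\t")
            sites.append(SiteAnnotation(int(pos), kind, float(prob), float(dur)))
    return sites
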