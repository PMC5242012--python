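"""Peptide records, cysteine frameworks and the synthetic library generator.

Venom peptides are short (here 35-120 residues), disulphide-rich chains.
The cysteine *framework* summarises how cysteines are arranged along the
primary sequence: adjacent cysteines are written ``CC``, others are joined
with dashes (e.g. ``C-C-CC-C-C``, the inhibitor-cystine-knot motif).  The
maximum number of disulphide bridges a peptide can form is ``floor(n_cys/2)``;
peptides with an odd cysteine count carry a flag because one thiol must stay
free (or pair inter-molecularly).

Because real toxin sequences from production campaigns are confidential, the
module also ships a generator that emulates such a library: lengths, bridge
counts, taxon mix and frameworks are sampled to match the composition of a
large venom-peptide production campaign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("venombank")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

TAXON_GROUPS = ("spider", "scorpion", "snake", "centipede", "cone_snail", "other")

#: Taxon composition of the emulated library (fractions of records).
DEFAULT_TAXON_MIX: Mapping[str, float] = {
    "spider": 0.43,
    "scorpion": 0.31,
    "snake": 0.10,
    "centipede": 0.07,
    "cone_snail": 0.06,
    "other": 0.03,
}

#: Length classes used by production reports (residues, inclusive bounds).
DEFAULT_LENGTH_CLASSES: tuple[tuple[int, int], ...] = (
    (35, 49),
    (50, 64),
    (65, 79),
    (80, 99),
    (100, 120),
)

#: Frameworks named in the field for common toxin folds: ICK, three-finger
#: (with and without the extra bridge), Cs-alpha/beta, Cs-alpha/alpha, C-C.
NAMED_FRAMEWORKS: tuple[str, ...] = (
    "C-C",
    "C-C-C-C",
    "C-C-C-C-C-C",
    "C-C-CC-C-C",
    "C-C-C-C-C-C-C-C",
    "C-C-C-C-C-CC-C",
    "C-C-C-C-C-C-C-CC-C",
)


class PeptideValidationError(ValueError):
    """A peptide sequence or record failed validation."""


def cysteine_pattern(sequence: str) -> str:
    """Project a sequence onto its cysteine framework string.

    Cysteines at consecutive residue positions are concatenated (``CC``);
    otherwise they are separated by ``-``.  Runs of three or more adjacent
    cysteines are rendered as that many concatenated ``C``'s.  Returns the
    empty string for cysteine-free sequences.
    """
    positions = [i for i, aa in enumerate(sequence) if aa == "C"]
    if not positions:
        return ""
    parts = ["C"]
    for prev, cur in zip(positions, positions[1:]):
        parts.append("C" if cur == prev + 1 else "-C")
    return "".join(parts)


@dataclass(frozen=True)
class BridgeCount:
    n_bridges: int
    odd_cysteines: bool


def bridge_count(n_cys: int) -> BridgeCount:
    """Maximum disulphide bridges for ``n_cys`` cysteines: floor(n_cys/2).

    The ``odd_cysteines`` flag marks peptides that cannot pair all thiols.
    """
    if n_cys < 0:
        raise ValueError(f"cysteine count must be non-negative, got {n_cys}")
    return BridgeCount(n_cys // 2, bool(n_cys % 2))


@dataclass(frozen=True)
class PeptideRecord:
    """One venom peptide with derived cysteine statistics."""

    id: str
    sequence: str
    taxon_group: str = "other"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise PeptideValidationError(
                f"record {self.id!r}: non-canonical amino-acid character(s) "
                f"{sorted(bad)}"
            )
        if self.taxon_group not in TAXON_GROUPS:
            raise PeptideValidationError(
                f"record {self.id!r}: unknown taxon group {self.taxon_group!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")

    @property
    def pattern(self) -> str:
        return cysteine_pattern(self.sequence)

    @property
    def n_bridges_max(self) -> int:
        return self.n_cys // 2

    @property
    def odd_cysteines(self) -> bool:
        return bool(self.n_cys % 2)

    @property
    def nterm(self) -> str:
        return self.sequence[0]


def read_peptides(path) -> list[PeptideRecord]:
    """Read peptide records from FASTA.

    The description line may carry ``key=value`` tokens; ``taxon=`` sets the
    taxon group (default ``other``).  Unknown keys are ignored with a warning.
    """
    records: list[PeptideRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        taxon = "other"
        for token in entry.description.split()[1:]:
            if "=" not in token:
                continue
            key, _, value = token.partition("=")
            if key == "taxon":
                taxon = value
            else:
                logger.warning("record %r: ignoring metadata key %r", entry.id, key)
        records.append(
            PeptideRecord(id=entry.id, sequence=str(entry.seq).upper(),
                          taxon_group=taxon)
        )
    if not records:
        raise PeptideValidationError(f"no FASTA records found in {path}")
    return records


def write_peptides_csv(records: Sequence[PeptideRecord], path) -> None:
    """Write the derived record table (id, taxon, length, cys stats) as CSV."""
    import pandas as pd

    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "taxon_group": [r.taxon_group for r in records],
            "length": [r.length for r in records],
            "n_cys": [r.n_cys for r in records],
            "pattern": [r.pattern for r in records],
            "n_bridges_max": [r.n_bridges_max for r in records],
            "odd_cysteines": [r.odd_cysteines for r in records],
        }
    ).to_csv(path, index=False)


def _framework_blocks(pattern: str) -> list[int]:
    """Block sizes of a framework string, e.g. 'C-CC-C' -> [1, 2, 1]."""
    if not pattern:
        return []
    return [len(block) for block in pattern.split("-")]


def _random_blocks(n_cys: int, rng: np.random.Generator,
                   pair_prob: float = 0.15) -> list[int]:
    """Partition ``n_cys`` cysteines into blocks of 1 or 2 (adjacent pairs)."""
    blocks: list[int] = []
    remaining = n_cys
    while remaining > 0:
        if remaining >= 2 and rng.random() < pair_prob:
            blocks.append(2)
            remaining -= 2
        else:
            blocks.append(1)
            remaining -= 1
    return blocks


def _place_framework(length: int, blocks: list[int],
                     rng: np.random.Generator) -> list[int] | None:
    """Choose cysteine positions realising ``blocks`` in a ``length`` chain.

    Blocks are separated by at least one non-cysteine residue.  Returns None
    when the framework does not fit.
    """
    n_blocks = len(blocks)
    n_cys = sum(blocks)
    free = length - n_cys - (n_blocks - 1)
    if free < 0:
        return None
    # distribute `free` spare residues over the n_blocks+1 gaps
    cuts = np.sort(rng.integers(0, free + 1, size=n_blocks))
    gaps = np.diff(np.concatenate(([0], cuts, [free])))
    positions: list[int] = []
    cursor = 0
    for i, size in enumerate(blocks):
        cursor += int(gaps[i]) + (1 if i > 0 else 0)
        positions.extend(range(cursor, cursor + size))
        cursor += size
    return positions


def generate_synthetic_library(
    n: int,
    seed: int,
    length_range: tuple[int, int] = (35, 120),
    bridge_range: tuple[int, int] = (1, 9),
    taxon_mix: Mapping[str, float] | None = None,
    odd_cys_prob: float = 0.02,
    named_framework_prob: float = 0.6,
    residue_weights: Mapping[str, float] | None = None,
    max_retries: int = 100,
) -> list[PeptideRecord]:
    """Generate a reproducible venom-like peptide library.

    Each record samples a taxon from ``taxon_mix``, a length uniform on
    ``length_range`` and a bridge count uniform on ``bridge_range``; cysteines
    are placed to realise a sampled framework (a field-named framework when
    one matches the cysteine count, otherwise a random one) and the remaining
    residues are drawn from ``residue_weights`` (uniform over the 19 non-Cys
    letters by default).  A small fraction (``odd_cys_prob``) of records carry
    an odd cysteine count, as observed in real venom libraries.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(taxon_mix or DEFAULT_TAXON_MIX)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"taxon proportions must sum to 1, got {total}")
    taxa = list(mix)
    probs = np.asarray([mix[t] for t in taxa], dtype=float)
    non_cys = [aa for aa in AMINO_ACIDS if aa != "C"]
    if residue_weights is None:
        res_probs = np.full(len(non_cys), 1.0 / len(non_cys))
    else:
        res_probs = np.asarray([residue_weights.get(aa, 0.0) for aa in non_cys])
        res_probs = res_probs / res_probs.sum()

    named_by_ncys: dict[int, list[str]] = {}
    for fw in NAMED_FRAMEWORKS:
        named_by_ncys.setdefault(sum(_framework_blocks(fw)), []).append(fw)

    rng = np.random.default_rng(seed)
    lo, hi = length_range
    b_lo, b_hi = bridge_range
    records: list[PeptideRecord] = []
    for i in range(n):
        taxon = taxa[int(rng.choice(len(taxa), p=probs))]
        length = int(rng.integers(lo, hi + 1))
        n_bridges = int(rng.integers(b_lo, b_hi + 1))
        n_cys = 2 * n_bridges + (1 if rng.random() < odd_cys_prob else 0)
        positions = None
        for _ in range(max_retries):
            named = named_by_ncys.get(n_cys, [])
            if named and rng.random() < named_framework_prob:
                fw = named[int(rng.integers(len(named)))]
                blocks = _framework_blocks(fw)
            else:
                blocks = _random_blocks(n_cys, rng)
            positions = _place_framework(length, blocks, rng)
            if positions is not None:
                break
        if positions is None:
            raise RuntimeError(
                f"could not place {n_cys} cysteines in a {length}-residue chain"
            )
        body = rng.choice(len(non_cys), size=length, p=res_probs)
        seq = [non_cys[int(j)] for j in body]
        for p in positions:
            seq[p] = "C"
        records.append(
            PeptideRecord(id=f"VP{i + 1:05d}", sequence="".join(seq),
                          taxon_group=taxon)
        )
    return records


def length_class(length: int,
                 classes: Sequence[tuple[int, int]] = DEFAULT_LENGTH_CLASSES) -> str:
    """Render the reporting bin for a peptide length, e.g. '35-49'."""
    for lo, hi in classes:
        if lo <= length <= hi:
            return f"{lo}-{hi}"
    return f"<{classes[0][0]}" if length < classes[0][0] else f">{classes[-1][1]}"
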