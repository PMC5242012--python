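"""PCR-assembly oligonucleotide tiling and in-silico reassembly.

Synthetic genes are assembled by PCR from overlapping oligonucleotides that
anneal via shared complementary ends.  The tiling geometry used here ("scheme
A", anchored at position 0 of the top strand) places, with period
``P = max_len + gap`` (default 60 + 20 = 80 nt):

* top-strand oligos ``i = 0..n_top-1`` spanning ``[P*i, min(P*i + max_len, L))``
  with ``n_top = ceil(L / P)``;
* internal bottom-strand oligos ``j = 0..n_top-2`` spanning
  ``[P*j + (max_len - overlap), P*j + (2*max_len - overlap))``;
* a terminal bottom-strand oligo from ``P*(n_top-1) + (max_len - overlap)``
  to ``L`` when that interval is non-empty.

Every junction between consecutive oligos is an exact ``overlap``-nt (default
20 nt) reverse-complement duplex; the terminal oligo may truncate to >= 15 nt
(shorter terminals are extended leftward into the duplex).  The two outermost
oligos double as the amplification primers.  For the emulated library (genes
of 137-413 nt, mean 220 nt) a 220-nt gene takes 6 oligos and a 137-nt gene 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

from .codon_design import reverse_complement

MIN_OLIGO_LEN = 15


@dataclass(frozen=True)
class Oligo:
    """One assembly oligonucleotide, coordinates on the top strand.

    ``sequence`` is written 5'->3' in its own strand: bottom-strand oligos
    are reverse complements of the top-strand slice ``[start, end)``.
    """

    index: int
    strand: str  # "top" | "bottom"
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OligoPlan:
    gene_id: str
    oligos: tuple[Oligo, ...]
    gene_length: int
    warnings: tuple[str, ...] = ()

    @property
    def n_oligos(self) -> int:
        return len(self.oligos)

    def coverage(self) -> list[int]:
        """Per-position count of covering oligos."""
        cov = [0] * self.gene_length
        for o in self.oligos:
            for p in range(o.start, o.end):
                cov[p] += 1
        return cov


def oligo_count(L: int, max_len: int = 60, overlap: int = 20,
                gap: int = 20) -> int:
    """Closed-form oligo count for a gene of length ``L`` under scheme A."""
    if L <= max_len - overlap:
        return 1
    P = max_len + gap
    n_top = ceil(L / P)
    terminal = 1 if L > P * (n_top - 1) + (max_len - overlap) else 0
    return n_top + (n_top - 1) + terminal


def design_oligos(gene: str, gene_id: str = "gene", max_len: int = 60,
                  overlap: int = 20, gap: int = 20) -> OligoPlan:
    """Tile a gene into assembly oligos under scheme A (see module docs)."""
    L = len(gene)
    warnings: list[str] = []
    lead = max_len - overlap  # offset of the bottom-strand series
    if L <= lead:
        warnings.append(
            f"gene of {L} nt (<= {lead}): single-oligo plan, no assembly"
        )
        oligo = Oligo(0, "top", 0, L, gene)
        return OligoPlan(gene_id, (oligo,), L, tuple(warnings))

    P = max_len + gap
    n_top = ceil(L / P)
    spans: list[tuple[str, int, int]] = []
    for i in range(n_top):
        spans.append(("top", P * i, min(P * i + max_len, L)))
    for j in range(n_top - 1):
        spans.append(("bottom", P * j + lead, min(P * j + lead + max_len, L)))
    t_start = P * (n_top - 1) + lead
    if L > t_start:
        spans.append(("bottom", t_start, L))

    spans.sort(key=lambda s: s[1])
    oligos: list[Oligo] = []
    for idx, (strand, start, end) in enumerate(spans):
        if end - start < MIN_OLIGO_LEN:  # extend leftward into the duplex
            start = end - MIN_OLIGO_LEN
        piece = gene[start:end]
        if strand == "bottom":
            piece = reverse_complement(piece)
        oligos.append(Oligo(idx, strand, start, end, piece))
    return OligoPlan(gene_id, tuple(oligos), L, tuple(warnings))


@dataclass(frozen=True)
class AssemblyReport:
    gene_id: str
    ok: bool
    reconstructed: str
    mismatch_at: int | None = None
    overlap_errors: tuple[str, ...] = ()
    mispriming_warnings: tuple[str, ...] = ()


def simulate_assembly(plan: OligoPlan, gene: str,
                      overlap: int = 20) -> AssemblyReport:
    """Verify that the oligo plan reassembles the gene exactly.

    Checks that consecutive oligos share an exact ``overlap``-nt (terminal
    >= 15 nt) reverse-complement duplex, stitches the top-strand consensus
    and compares it with the gene, and flags any junction 20-mer that occurs
    more than once in the gene (mispriming risk during PCR assembly).
    """
    oligos = sorted(plan.oligos, key=lambda o: o.start)
    overlap_errors: list[str] = []
    mispriming: list[str] = []

    # per-oligo sequence fidelity, reported as the first divergent coordinate
    mismatch_at: int | None = None
    consensus = list("N" * len(gene))
    for o in oligos:
        top = o.sequence if o.strand == "top" else reverse_complement(o.sequence)
        for k, base in enumerate(top):
            pos = o.start + k
            if pos >= len(gene):
                mismatch_at = mismatch_at if mismatch_at is not None else pos
                break
            if consensus[pos] != "N" and consensus[pos] != base:
                if mismatch_at is None or pos < mismatch_at:
                    mismatch_at = pos
            consensus[pos] = base

    for a, b in zip(oligos, oligos[1:]):
        if a.strand == b.strand:
            overlap_errors.append(
                f"oligos {a.index} and {b.index} are on the same strand"
            )
            continue
        ov_start, ov_end = max(a.start, b.start), min(a.end, b.end)
        ov_len = ov_end - ov_start
        is_terminal = b is oligos[-1] or a is oligos[0]
        if ov_len != overlap and not (is_terminal
                                      and MIN_OLIGO_LEN <= ov_len <= overlap):
            overlap_errors.append(
                f"junction {a.index}/{b.index}: overlap {ov_len} nt "
                f"(expected {overlap})"
            )
            continue
        duplex = gene[ov_start:ov_end]
        if len(duplex) == ov_len and gene.count(duplex) > 1:
            mispriming.append(
                f"junction {a.index}/{b.index}: {ov_len}-mer occurs "
                f"{gene.count(duplex)} times in the gene"
            )

    reconstructed = "".join(consensus)
    if mismatch_at is None and reconstructed != gene:
        mismatch_at = next(
            (i for i, (x, y) in enumerate(zip(reconstructed, gene)) if x != y),
            min(len(reconstructed), len(gene)),
        )
    ok = mismatch_at is None and not overlap_errors and reconstructed == gene
    return AssemblyReport(
        gene_id=plan.gene_id,
        ok=ok,
        reconstructed=reconstructed,
        mismatch_at=mismatch_at,
        overlap_errors=tuple(overlap_errors),
        mispriming_warnings=tuple(mispriming),
    )


def plans_to_rows(plans: Sequence[OligoPlan]) -> list[dict]:
    """Flatten plans for CSV export (gene_id, index, strand, coords, seq)."""
    rows = []
    for plan in plans:
        for o in plan.oligos:
            rows.append(
                {
                    "gene_id": plan.gene_id,
                    "index": o.index,
                    "strand": o.strand,
                    "start": o.start,
                    "end": o.end,
                    "length": o.length,
                    "sequence": o.sequence,
                }
            )
    return rows
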