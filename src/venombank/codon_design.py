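"""Back-translation and codon optimization for E. coli expression.

Genes are designed as: TEV-site DNA prefix (``GAGAACCTGTACTTCCAA`` encoding
ENLYFQ) + one codon per peptide residue + a duplicated TAA stop (``TAATAA``).
Optimization starts from the most-adapted codon for every residue (cysteines
alternate TGC/TGT so the two codons are used in equal proportion) and then
repairs constraint violations by single-codon synonymous substitutions:

* global GC content within 40-60 %
* no run of identical bases longer than 5 nt
* no run over the {G,C} alphabet longer than 6 nt
* no occurrence of forbidden regulatory motifs (either strand)
* no codon with relative adaptiveness w below a floor (default 0.1)
* |#TGC - #TGT| <= 1
* Codon Adaptation Index (CAI) >= 0.8

CAI is the geometric mean of the relative adaptiveness w of the scored
codons, where w(codon) = f(codon) / max f over its synonymous family in a
reference set of highly expressed genes.  Met, Trp and stop codons are
excluded from scoring by default (the Sharp & Li convention; switchable).

Repairs pick the substitution with the highest resulting w (ties broken by
higher codon frequency, then alphabetical codon order; exact ties and the
violation visit order are the only uses of the seeded RNG) and never increase
the number of violated constraints.  When the constraint set is unsatisfiable
the design is returned with explicit failed flags instead of raising.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from math import exp, log
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

TEV_PREFIX_DNA = "GAGAACCTGTACTTCCAA"  # encodes ENLYFQ
STOP_SUFFIX = "TAATAA"  # duplicated TAA stop

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate coding DNA up to (and excluding) the first stop codon."""
    return str(Seq(dna).translate(to_stop=True))


class CodonTableError(ValueError):
    pass


@dataclass(frozen=True)
class CodonTable:
    """Codon usage table with derived relative adaptiveness.

    ``frequency`` maps each sense codon to its usage (per-thousand or
    fraction -- w is scale-invariant); ``aa_of`` maps codon to amino acid.
    """

    frequency: Mapping[str, float]
    aa_of: Mapping[str, str]

    def __post_init__(self) -> None:
        sense = {c for c, aa in self.aa_of.items() if aa != "*"}
        if len(sense) != 61:
            raise CodonTableError(
                f"codon table must contain all 61 sense codons, got {len(sense)}"
            )
        for codon, f in self.frequency.items():
            if f < 0:
                raise CodonTableError(f"negative frequency for {codon}")

    @property
    def families(self) -> dict[str, list[str]]:
        """Synonymous codons per amino acid (sense codons only)."""
        fam: dict[str, list[str]] = {}
        for codon, aa in self.aa_of.items():
            if aa != "*":
                fam.setdefault(aa, []).append(codon)
        for codons in fam.values():
            codons.sort()
        return fam

    @classmethod
    def from_file(cls, path) -> "CodonTable":
        """Read a delimited (tab or comma) codon,aa,frequency table."""
        freq: dict[str, float] = {}
        aa_of: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", "\t").split("\t")
                if len(parts) < 3:
                    raise CodonTableError(f"malformed codon table line: {line!r}")
                codon, aa, f = parts[0].upper().replace("U", "T"), parts[1], parts[2]
                freq[codon] = float(f)
                aa_of[codon] = aa
        return cls(frequency=freq, aa_of=aa_of)

    @classmethod
    def default(cls) -> "CodonTable":
        """The packaged E. coli K-12 usage table."""
        ref = importlib.resources.files("venombank.data") / "ecoli_codon_usage.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path)


def relative_adaptiveness(table: CodonTable) -> dict[str, float]:
    """w(codon) = f(codon) / max f over its synonymous family."""
    w: dict[str, float] = {}
    for aa, codons in table.families.items():
        fmax = max(table.frequency[c] for c in codons)
        if fmax == 0:
            raise CodonTableError(f"all-zero frequencies for amino acid {aa}")
        for c in codons:
            w[c] = table.frequency[c] / fmax
    return w


def cai(dna: str, table: CodonTable,
        exclude: Iterable[str] = ("M", "W")) -> float:
    """Codon Adaptation Index: geometric mean of w over scored codons.

    Codons for amino acids in ``exclude`` (default Met and Trp, which have no
    synonyms) and stop codons are not scored.  Terminal stop codons are
    tolerated; an internal in-frame stop raises.
    """
    if len(dna) % 3:
        raise ValueError("coding DNA length must be divisible by 3")
    w = relative_adaptiveness(table)
    excluded = set(exclude)
    codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
    # strip terminal stop codon(s)
    while codons and table.aa_of.get(codons[-1]) == "*":
        codons.pop()
    logs = []
    for i, codon in enumerate(codons):
        aa = table.aa_of.get(codon)
        if aa is None:
            raise ValueError(f"unknown codon {codon!r} at position {3 * i}")
        if aa == "*":
            raise ValueError(f"internal in-frame stop codon at position {3 * i}")
        if aa in excluded:
            continue
        if w[codon] <= 0:
            raise ValueError(f"codon {codon} has zero adaptiveness")
        logs.append(log(w[codon]))
    if not logs:
        return 1.0
    return exp(sum(logs) / len(logs))


def gc_content(dna: str) -> float:
    """GC content in percent: 100 * (G+C) / length."""
    if not dna:
        raise ValueError("empty DNA")
    return 100.0 * (dna.count("G") + dna.count("C")) / len(dna)


def max_run(dna: str, mode: str = "homopolymer") -> int:
    """Longest run: of one identical base ('homopolymer') or over {G,C}
    ('gc_run')."""
    if not dna:
        raise ValueError("empty DNA")
    if mode == "homopolymer":
        best = cur = 1
        for a, b in zip(dna, dna[1:]):
            cur = cur + 1 if a == b else 1
            best = max(best, cur)
        return best
    if mode == "gc_run":
        best = cur = 0
        for base in dna:
            cur = cur + 1 if base in "GC" else 0
            best = max(best, cur)
        return best
    raise ValueError(f"unknown run mode {mode!r}")


def screen_motifs(dna: str, motifs: Sequence[str]) -> list[tuple[str, int, str]]:
    """All exact motif occurrences on the given strand and its reverse
    complement, as (motif, 0-based top-strand position, strand)."""
    hits: list[tuple[str, int, str]] = []
    for motif in motifs:
        motif = motif.upper()
        for query, strand in ((motif, "+"), (reverse_complement(motif), "-")):
            if strand == "-" and query == motif:  # palindromes once
                continue
            start = dna.find(query)
            while start != -1:
                hits.append((motif, start, strand))
                start = dna.find(query, start + 1)
    hits.sort(key=lambda h: (h[1], h[2], h[0]))
    return hits


@dataclass(frozen=True)
class DesignConstraints:
    """The desk rule set a synthesized gene must satisfy."""

    gc_min: float = 40.0
    gc_max: float = 60.0
    cai_min: float = 0.8
    max_gc_run: int = 6
    max_homopolymer: int = 5
    balance_cys_codons: bool = True
    rare_codon_w_floor: float = 0.1
    forbidden_motifs: tuple[str, ...] = ("TATAAT", "AGGAGG")
    tev_prefix_dna: str = TEV_PREFIX_DNA
    stop_suffix: str = STOP_SUFFIX

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min < self.gc_max <= 100):
            raise ValueError("require 0 <= gc_min < gc_max <= 100")
        if not (0 < self.cai_min <= 1):
            raise ValueError("cai_min must be in (0, 1]")
        if self.max_gc_run < 1 or self.max_homopolymer < 1:
            raise ValueError("run limits must be >= 1")


CONSTRAINT_NAMES = (
    "gc", "cai", "homopolymer", "gc_run", "motifs", "rare_codons", "cys_balance",
)


@dataclass(frozen=True)
class GeneDesign:
    """Optimized DNA for one peptide."""

    peptide_id: str
    cds: str
    cai: float
    gc_percent: float
    max_gc_run_observed: int
    max_homopolymer_observed: int
    motif_hits: tuple[tuple[str, int, str], ...]
    constraint_flags: Mapping[str, bool]  # True = rule satisfied
    seed: int
    iterations: int = 0

    @property
    def passes_all(self) -> bool:
        return all(self.constraint_flags.values())

    @property
    def peptide_cds(self) -> str:
        """The peptide-encoding portion (prefix and stop suffix stripped)."""
        return self.cds[len(TEV_PREFIX_DNA):-len(STOP_SUFFIX)]


def back_translate_initial(peptide: str, table: CodonTable) -> str:
    """Most-adapted codon per residue; cysteines alternate TGC/TGT.

    The alternation starts with the globally more frequent cysteine codon so
    that |#TGC - #TGT| <= 1 in every gene.
    """
    w = relative_adaptiveness(table)
    families = table.families
    best: dict[str, str] = {}
    for aa, codons in families.items():
        best[aa] = max(codons, key=lambda c: (w[c], table.frequency[c],
                                              _alpha_key(c)))
    cys_order = (["TGC", "TGT"]
                 if table.frequency["TGC"] >= table.frequency["TGT"]
                 else ["TGT", "TGC"])
    out: list[str] = []
    cys_i = 0
    for aa in peptide:
        if aa == "C":
            out.append(cys_order[cys_i % 2])
            cys_i += 1
        else:
            if aa not in best:
                raise ValueError(f"cannot back-translate residue {aa!r}")
            out.append(best[aa])
    return "".join(out)


def _alpha_key(codon: str) -> tuple[int, ...]:
    # reversed ordinal so that max() picks the alphabetically FIRST codon
    return tuple(-ord(ch) for ch in codon)


def _violations(cds: str, table: CodonTable, cons: DesignConstraints,
                w: Mapping[str, float], mutable: range) -> dict[str, bool]:
    """Pass/fail flags per constraint (True = satisfied)."""
    gc = gc_content(cds)
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    n_tgc = sum(c == "TGC" for c in codons)
    n_tgt = sum(c == "TGT" for c in codons)
    rare_ok = all(
        w.get(codons[i // 3], 1.0) >= cons.rare_codon_w_floor
        for i in mutable
    )
    return {
        "gc": cons.gc_min <= gc <= cons.gc_max,
        "cai": cai(cds, table) >= cons.cai_min,
        "homopolymer": max_run(cds, "homopolymer") <= cons.max_homopolymer,
        "gc_run": max_run(cds, "gc_run") <= cons.max_gc_run,
        "motifs": not screen_motifs(cds, cons.forbidden_motifs),
        "rare_codons": rare_ok,
        "cys_balance": (not cons.balance_cys_codons) or abs(n_tgc - n_tgt) <= 1,
    }


def _runs(dna: str, mode: str) -> list[tuple[int, int]]:
    """Coordinates [start, end) of maximal runs for the given mode."""
    spans: list[tuple[int, int]] = []
    i = 0
    n = len(dna)
    while i < n:
        if mode == "gc_run" and dna[i] not in "GC":
            i += 1
            continue
        j = i + 1
        if mode == "homopolymer":
            while j < n and dna[j] == dna[i]:
                j += 1
        else:
            while j < n and dna[j] in "GC":
                j += 1
        spans.append((i, j))
        i = j
    return spans


def _codon_positions_overlapping(span: tuple[int, int],
                                 mutable: range) -> list[int]:
    """Mutable codon indices whose nt range intersects [start, end)."""
    start, end = span
    first = start // 3
    last = (end - 1) // 3
    lo, hi = mutable.start // 3, (mutable.stop // 3) - 1
    return [k for k in range(max(first, lo), min(last, hi) + 1)]


def optimize(peptide, table: CodonTable | None = None,
             constraints: DesignConstraints | None = None,
             seed: int = 0, max_iterations: int | None = None) -> GeneDesign:
    """Design the synthesized gene for one peptide.

    ``peptide`` may be a :class:`~venombank.peptide_io.PeptideRecord` or a
    plain sequence string.  The TEV prefix and duplicated stop are immutable;
    repairs operate on peptide codons only.  Always returns a design -- unmet
    constraints are reported through ``constraint_flags``.
    """
    pid = getattr(peptide, "id", "peptide")
    seq = getattr(peptide, "sequence", peptide)
    if not seq:
        raise ValueError("peptide must have length >= 1")
    table = table or CodonTable.default()
    cons = constraints or DesignConstraints()
    if max_iterations is None:
        max_iterations = 10 * len(seq)
    rng = np.random.default_rng(seed)
    w = relative_adaptiveness(table)
    families = table.families

    prefix, suffix = cons.tev_prefix_dna, cons.stop_suffix
    cds = prefix + back_translate_initial(seq, table) + suffix
    mutable = range(len(prefix), len(cds) - len(suffix))  # nt coordinates

    def synonyms(codon_idx: int) -> list[str]:
        aa = table.aa_of[cds[3 * codon_idx:3 * codon_idx + 3]]
        return [c for c in families[aa]
                if c != cds[3 * codon_idx:3 * codon_idx + 3]]

    def splice(codon_idx: int, codon: str) -> str:
        i = 3 * codon_idx
        return cds[:i] + codon + cds[i + 3:]

    def candidate_positions(name: str, flags: dict[str, bool]) -> list[int]:
        lo, hi = mutable.start // 3, mutable.stop // 3
        allc = list(range(lo, hi))
        if name == "gc":
            return allc
        if name == "cai":
            return sorted(allc, key=lambda k: w.get(cds[3 * k:3 * k + 3], 1.0))
        if name in ("homopolymer", "gc_run"):
            limit = (cons.max_homopolymer if name == "homopolymer"
                     else cons.max_gc_run)
            out: list[int] = []
            for span in _runs(cds, name):
                if span[1] - span[0] > limit:
                    out.extend(_codon_positions_overlapping(span, mutable))
            return out
        if name == "motifs":
            out = []
            for motif, pos, _ in screen_motifs(cds, cons.forbidden_motifs):
                out.extend(_codon_positions_overlapping(
                    (pos, pos + len(motif)), mutable))
            return sorted(set(out))
        if name == "rare_codons":
            return [k for k in allc
                    if w.get(cds[3 * k:3 * k + 3], 1.0) < cons.rare_codon_w_floor]
        if name == "cys_balance":
            codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
            majority = ("TGC" if codons.count("TGC") > codons.count("TGT")
                        else "TGT")
            return [k for k in allc if cds[3 * k:3 * k + 3] == majority]
        raise AssertionError(name)

    HARD = ("homopolymer", "gc_run", "motifs", "rare_codons", "cys_balance")

    def severity(flags: dict[str, bool], dna: str) -> tuple[int, float]:
        """(violated hard constraints, graded badness) -- lower is better.

        Hard sequence constraints never regress across accepted repairs;
        the graded score constraints (GC window, CAI) are driven down
        through ``badness`` and may trade against each other transiently.
        """
        n_bad = sum(not flags[name] for name in HARD)
        gc = gc_content(dna)
        run_excess = sum(
            max(0, (b - a) - cons.max_homopolymer)
            for a, b in _runs(dna, "homopolymer")
        ) + sum(
            max(0, (b - a) - cons.max_gc_run) for a, b in _runs(dna, "gc_run")
        )
        codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
        cys_excess = max(0, abs(codons.count("TGC") - codons.count("TGT")) - 1)
        badness = (
            max(0.0, cons.gc_min - gc) + max(0.0, gc - cons.gc_max)
            + run_excess
            + len(screen_motifs(dna, cons.forbidden_motifs))
            + max(0.0, cons.cai_min - cai(dna, table)) * 10
            + (cys_excess if cons.balance_cys_codons else 0)
        )
        return n_bad, badness

    iterations = 0
    for iterations in range(1, max_iterations + 1):
        flags = _violations(cds, table, cons, w, mutable)
        if all(flags.values()):
            break
        violated = [name for name in CONSTRAINT_NAMES if not flags[name]]
        visit = [violated[i] for i in rng.permutation(len(violated))]
        cur_sev = severity(flags, cds)
        accepted = False
        for name in visit:
            best_choice: list[tuple[tuple, int, str, str]] = []
            for k in candidate_positions(name, flags):
                for alt in synonyms(k):
                    trial = splice(k, alt)
                    t_flags = _violations(trial, table, cons, w, mutable)
                    t_sev = severity(t_flags, trial)
                    if t_sev[0] > cur_sev[0] or t_sev >= cur_sev:
                        continue  # strict improvement, hard flags never added
                    key = (-w[alt], -table.frequency[alt], alt)
                    best_choice.append((key, k, alt, trial))
            if best_choice:
                best_choice.sort(key=lambda t: t[0])
                top_key = best_choice[0][0]
                tied = [t for t in best_choice if t[0] == top_key]
                _, k, alt, trial = tied[int(rng.integers(len(tied)))]
                cds = trial
                accepted = True
                break
        if not accepted:
            break  # no improving single-codon move exists

    flags = _violations(cds, table, cons, w, mutable)
    return GeneDesign(
        peptide_id=pid,
        cds=cds,
        cai=cai(cds, table),
        gc_percent=gc_content(cds),
        max_gc_run_observed=max_run(cds, "gc_run"),
        max_homopolymer_observed=max_run(cds, "homopolymer"),
        motif_hits=tuple(screen_motifs(cds, cons.forbidden_motifs)),
        constraint_flags=dict(flags),
        seed=seed,
        iterations=iterations,
    )


def design_library(records, table: CodonTable | None = None,
                   constraints: DesignConstraints | None = None,
                   seed: int = 0) -> list[GeneDesign]:
    """Optimize every record; per-gene seeds are derived from ``seed``."""
    table = table or CodonTable.default()
    return [optimize(rec, table, constraints, seed=(seed + i) % (2**31))
            for i, rec in enumerate(records)]
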