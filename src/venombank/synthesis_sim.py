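"""Gene-synthesis error simulation and colony-screening statistics.

PCR-assembled synthetic genes accumulate errors introduced during chemical
oligonucleotide synthesis.  The model is a Poisson process along the gene:
the number of errors in a clone of length L is Poisson(rate * L / 1000)
with a default rate of 1.06 errors/kb, and each error is a single-base event
drawn from the observed spectrum -- deletions 76 %, insertions 7 %,
substitutions 17 % (deletions dominate because truncated oligos are
incorporated during assembly).

Screening follows the sequential policy used at the bench: sequence one
colony per cloning reaction, and pick a second and at most a third only when
no correct clone has been found.  The Poisson model gives the closed-form
oracle P(correct clone) = exp(-rate * L / 1000), against which the simulator
is validated.  Two errors/kb estimators are provided: a naive one (each
incorrect clone counted as one error over the kb sequenced) and a maximum-
likelihood one (-ln p_hat over the mean gene length in kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log
from typing import Mapping, Sequence

import numpy as np

from .bank_triage import round_half_away

BASES = "ACGT"


@dataclass(frozen=True)
class ErrorModel:
    """Single-base error process for gene synthesis."""

    rate_per_kb: float = 1.06
    spectrum: Mapping[str, float] = field(
        default_factory=lambda: {"deletion": 0.76, "insertion": 0.07,
                                 "substitution": 0.17}
    )
    #: optional per-base weights for which base is inserted / deleted /
    #: substituted-in (uniform when None)
    base_bias: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.rate_per_kb < 0:
            raise ValueError("error rate must be non-negative")
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"error spectrum must sum to 1, got {total}")


@dataclass(frozen=True)
class ScreeningPolicy:
    max_colonies: int = 3

    def __post_init__(self) -> None:
        if self.max_colonies < 1:
            raise ValueError("max_colonies must be >= 1")


@dataclass(frozen=True)
class SynthesisError:
    kind: str  # deletion | insertion | substitution
    position: int
    ref: str
    alt: str  # "" for deletions


def mutate_clone(gene: str, model: ErrorModel,
                 rng: np.random.Generator) -> tuple[str, list[SynthesisError]]:
    """Draw one clone of ``gene`` under the error model.

    Error count ~ Poisson(rate * L / 1000); positions uniform; types by
    spectrum.  Deletions remove one base, insertions add one base before the
    position, substitutions replace with a different base.
    """
    L = len(gene)
    n_errors = int(rng.poisson(model.rate_per_kb * L / 1000.0))
    if n_errors == 0:
        return gene, []
    kinds = list(model.spectrum)
    kind_p = np.array([model.spectrum[k] for k in kinds])
    if model.base_bias is None:
        base_p = np.full(4, 0.25)
    else:
        base_p = np.array([model.base_bias.get(b, 0.0) for b in BASES])
        base_p = base_p / base_p.sum()

    events = []
    for _ in range(n_errors):
        pos = int(rng.integers(L))
        kind = kinds[int(rng.choice(len(kinds), p=kind_p))]
        events.append((pos, kind))
    # apply right-to-left so earlier coordinates stay valid
    seq = list(gene)
    errors: list[SynthesisError] = []
    for pos, kind in sorted(events, reverse=True):
        if kind != "insertion":
            pos = min(pos, len(seq) - 1)  # earlier deletion may have shrunk seq
        if kind == "deletion":
            ref = seq[pos]
            del seq[pos]
            errors.append(SynthesisError("deletion", pos, ref, ""))
        elif kind == "insertion":
            alt = BASES[int(rng.choice(4, p=base_p))]
            seq.insert(pos, alt)
            errors.append(SynthesisError("insertion", pos, "", alt))
        else:
            ref = seq[pos]
            others = [b for b in BASES if b != ref]
            p = np.array([base_p[BASES.index(b)] for b in others])
            if p.sum() == 0:
                p = np.full(3, 1 / 3)
            alt = others[int(rng.choice(3, p=p / p.sum()))]
            seq[pos] = alt
            errors.append(SynthesisError("substitution", pos, ref, alt))
    errors.reverse()
    return "".join(seq), errors


@dataclass(frozen=True)
class SimResult:
    """Aggregate outcome of simulated colony screening."""

    total_genes: int
    correct_at_colony: tuple[int, ...]  # counts at colony 1, 2, ...
    recovered: int
    fraction_correct_at: tuple[float, ...]
    overall_recovery: float
    mean_colonies_among_recovered: float
    error_type_counts: Mapping[str, int]
    errors_per_kb_naive: float
    errors_per_kb_ml: float
    per_gene: tuple[tuple[str, int, bool], ...]  # (id, colonies, recovered)


def simulate_screening(genes: Mapping[str, str] | Sequence[str],
                       model: ErrorModel | None = None,
                       policy: ScreeningPolicy | None = None,
                       seed: int = 0) -> SimResult:
    """Simulate sequential colony screening for a gene library."""
    model = model or ErrorModel()
    policy = policy or ScreeningPolicy()
    if not genes:
        raise ValueError("no genes to screen")
    if isinstance(genes, Mapping):
        items = list(genes.items())
    else:
        items = [(f"g{i + 1}", g) for i, g in enumerate(genes)]

    rng = np.random.default_rng(seed)
    correct_at = [0] * policy.max_colonies
    type_counts = {"deletion": 0, "insertion": 0, "substitution": 0}
    per_gene = []
    total_nt_screened = 0
    incorrect_clones = 0
    for gid, gene in items:
        recovered = False
        colonies = 0
        for c in range(1, policy.max_colonies + 1):
            colonies = c
            clone, errs = mutate_clone(gene, model, rng)
            total_nt_screened += len(gene)
            for e in errs:
                type_counts[e.kind] += 1
            if clone == gene:
                correct_at[c - 1] += 1
                recovered = True
                break
            incorrect_clones += 1
        per_gene.append((gid, colonies, recovered))

    total = len(items)
    recovered_n = sum(correct_at)
    mean_col = (
        sum((k + 1) * c for k, c in enumerate(correct_at)) / recovered_n
        if recovered_n else float("nan")
    )
    mean_kb = float(np.mean([len(g) for _, g in items])) / 1000.0
    p1 = correct_at[0] / total
    ml = -log(p1) / mean_kb if p1 > 0 else float("inf")
    naive = incorrect_clones / (total_nt_screened / 1000.0)
    return SimResult(
        total_genes=total,
        correct_at_colony=tuple(correct_at),
        recovered=recovered_n,
        fraction_correct_at=tuple(c / total for c in correct_at),
        overall_recovery=recovered_n / total,
        mean_colonies_among_recovered=mean_col,
        error_type_counts=type_counts,
        errors_per_kb_naive=naive,
        errors_per_kb_ml=ml,
        per_gene=tuple(per_gene),
    )


def analytic_correct_prob(rate_per_kb: float, L: int) -> float:
    """Poisson oracle: P(zero errors) = exp(-rate * L / 1000)."""
    if rate_per_kb < 0 or L < 1:
        raise ValueError("rate must be >= 0 and L >= 1")
    return exp(-rate_per_kb * L / 1000.0)


@dataclass(frozen=True)
class ScreeningStatistics:
    fractions_pct: tuple[float, ...]  # percent, one decimal
    mean_colonies: float  # one decimal
    recovered: int
    total: int


def screening_statistics(counts: Sequence[int], total: int) -> ScreeningStatistics:
    """Cascade statistics from correct-at-colony-k counts.

    ``counts[k]`` is the number of genes first found correct at colony k+1.
    Fractions are percentages of ``total``; the mean number of colonies
    screened per recovered gene is reported to one decimal.
    """
    if any(c < 0 for c in counts) or total <= 0:
        raise ValueError("counts must be non-negative and total positive")
    recovered = sum(counts)
    if recovered > total:
        raise ValueError("counts sum exceeds total")
    fractions = tuple(
        round_half_away(1000.0 * c / total) / 10 for c in counts
    )
    mean = (sum((k + 1) * c for k, c in enumerate(counts)) / recovered
            if recovered else float("nan"))
    return ScreeningStatistics(
        fractions_pct=fractions,
        mean_colonies=round_half_away(mean * 10) / 10,
        recovered=recovered,
        total=total,
    )
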