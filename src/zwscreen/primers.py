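"""Primer quality constraints, pair enumeration and multiplex compatibility.

Constraint defaults mirror a conventional marker-PCR design: Tm 59-61 deg C
(optimum 60), pair Tm difference <= 1, no homopolymer longer than 3, a
single-base 3' G/C clamp, and a product of 480-520 bp (optimum 500).
Enumeration is exhaustive over all primer windows within the length bounds,
so results are deterministic and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .thermo import melting_temperature, reverse_complement

__all__ = [
    "DesignConstraints",
    "Primer",
    "PrimerPair",
    "PairSearchResult",
    "primer_quality",
    "enumerate_candidate_pairs",
    "multiplex_compatible",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class DesignConstraints:
    tm_min: float = 59.0
    tm_opt: float = 60.0
    tm_max: float = 61.0
    tm_pair_max_diff: float = 1.0
    max_poly_x: int = 3
    gc_clamp: int = 1
    product_min: int = 480
    product_opt: int = 500
    product_max: int = 520
    primer_len_min: int = 18
    primer_len_max: int = 27
    na_mM: float = 50.0
    oligo_nM: float = 500.0

    def __post_init__(self) -> None:
        if not self.tm_min <= self.tm_opt <= self.tm_max:
            raise ValueError("need tm_min <= tm_opt <= tm_max")
        if not self.product_min <= self.product_opt <= self.product_max:
            raise ValueError("need product_min <= product_opt <= product_max")
        if not 0 < self.primer_len_min <= self.primer_len_max:
            raise ValueError("invalid primer length bounds")


@dataclass(frozen=True)
class Primer:
    """A single oligo, 5'->3', with template position and quality numbers."""

    sequence: str
    template_start: int  # 0-based position of the 5'-most template base covered
    strand: str  # '+' binds the minus strand (forward), '-' is a reverse primer
    tm_c: float
    gc_fraction: float
    max_run: int
    clamp_ok: bool

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    product_bp: int
    tm_diff: float
    score: float


@dataclass
class PairSearchResult:
    """Ranked feasible pairs plus a per-criterion failure tally.

    When ``pairs`` is empty, ``failure_counts`` explains what eliminated the
    search space (e.g. ``template_too_short``, ``tm_out_of_range``).
    """

    pairs: list[PrimerPair] = field(default_factory=list)
    failure_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def primer_quality(
    sequence: str, constraints: DesignConstraints | None = None
) -> dict:
    """Evaluate one primer sequence against the design constraints.

    Returns ``tm_c``, ``gc_fraction``, ``max_run`` and the boolean flags
    ``tm_ok`` (Tm within [tm_min, tm_max]), ``run_ok`` (longest homopolymer
    <= max_poly_x) and ``clamp_ok`` (the ``gc_clamp`` 3'-terminal bases are
    all G/C).
    """
    c = constraints or DesignConstraints()
    tm = melting_temperature(sequence, na_mM=c.na_mM, oligo_nM=c.oligo_nM)
    gc = sum(sequence.count(b) for b in "GC") / len(sequence)
    run = _max_homopolymer(sequence)
    clamp = all(b in "GC" for b in sequence[len(sequence) - c.gc_clamp :])
    return {
        "tm_c": tm,
        "gc_fraction": gc,
        "max_run": run,
        "tm_ok": c.tm_min <= tm <= c.tm_max,
        "run_ok": run <= c.max_poly_x,
        "clamp_ok": clamp,
    }


def _scan_windows(template: str, constraints: DesignConstraints, strand: str, tally: dict):
    """All quality-passing primers on one strand; tallies each failure mode."""
    n = len(template)
    out = []
    for length in range(constraints.primer_len_min, constraints.primer_len_max + 1):
        for start in range(0, n - length + 1):
            window = template[start : start + length]
            if "N" in window:
                tally["ambiguous_base"] = tally.get("ambiguous_base", 0) + 1
                continue
            seq = window if strand == "+" else reverse_complement(window)
            q = primer_quality(seq, constraints)
            if not q["tm_ok"]:
                tally["tm_out_of_range"] = tally.get("tm_out_of_range", 0) + 1
                continue
            if not q["run_ok"]:
                tally["homopolymer_run"] = tally.get("homopolymer_run", 0) + 1
                continue
            if not q["clamp_ok"]:
                tally["gc_clamp"] = tally.get("gc_clamp", 0) + 1
                continue
            out.append(
                Primer(
                    sequence=seq,
                    template_start=start,
                    strand=strand,
                    tm_c=q["tm_c"],
                    gc_fraction=q["gc_fraction"],
                    max_run=q["max_run"],
                    clamp_ok=True,
                )
            )
    return out


def enumerate_candidate_pairs(
    template: str, constraints: DesignConstraints | None = None
) -> PairSearchResult:
    """Exhaustively enumerate feasible primer pairs on a template.

    A pair is feasible when both primers pass quality, the 5'-to-5' product
    span lies within [product_min, product_max], and the pair Tm difference
    is within tm_pair_max_diff.  Pairs are ranked by
    ``|Tm_f - tm_opt| + |Tm_r - tm_opt| + |product - product_opt| / 100``,
    ties broken by leftmost forward start then product size.
    """
    c = constraints or DesignConstraints()
    template = template.upper()
    tally: dict[str, int] = {}
    if len(template) < c.product_min:
        return PairSearchResult(failure_counts={"template_too_short": 1})

    forwards = _scan_windows(template, c, "+", tally)
    reverses = _scan_windows(template, c, "-", tally)
    # index reverse primers by the template position of their 3'-most span end
    by_end: dict[int, list[Primer]] = {}
    for r in reverses:
        by_end.setdefault(r.template_start + len(r) - 1, []).append(r)

    pairs: list[PrimerPair] = []
    n_product_miss = n_tm_diff = 0
    for f in forwards:
        for product in range(c.product_min, c.product_max + 1):
            end = f.template_start + product - 1
            if end >= len(template):
                continue
            for r in by_end.get(end, []):
                if r.template_start < f.template_start + len(f):
                    continue  # overlapping primers
                tm_diff = abs(f.tm_c - r.tm_c)
                if tm_diff > c.tm_pair_max_diff:
                    n_tm_diff += 1
                    continue
                score = (
                    abs(f.tm_c - c.tm_opt)
                    + abs(r.tm_c - c.tm_opt)
                    + abs(product - c.product_opt) / 100.0
                )
                pairs.append(PrimerPair(f, r, product, tm_diff, score))
    if not pairs:
        if not forwards or not reverses:
            tally.setdefault("no_quality_primer_on_a_strand", 1)
        if n_tm_diff:
            tally["pair_tm_difference"] = n_tm_diff
        if forwards and reverses and not n_tm_diff:
            tally["no_product_in_range"] = n_product_miss or 1
    pairs.sort(key=lambda p: (p.score, p.forward.template_start, p.product_bp))
    return PairSearchResult(pairs=pairs, failure_counts=tally)


def multiplex_compatible(
    pairs, control_product_bp: int, min_separation_bp: int = 40
) -> tuple[bool, list[tuple[int, int]]]:
    """Check that multiplexed products are distinguishable on a gel.

    ``pairs`` may be PrimerPair objects or raw product sizes.  Compatible iff
    every pairwise candidate-product difference is >= ``min_separation_bp``
    and the control product is strictly smaller than every candidate
    product.  Returns ``(ok, conflicts)`` where conflicts are offending
    product-size pairs (the control listed as its size).
    """
    products = [p.product_bp if isinstance(p, PrimerPair) else int(p) for p in pairs]
    conflicts: list[tuple[int, int]] = []
    for i in range(len(products)):
        for j in range(i + 1, len(products)):
            if abs(products[i] - products[j]) < min_separation_bp:
                conflicts.append((products[i], products[j]))
    for p in products:
        if control_product_bp >= p:
            conflicts.append((control_product_bp, p))
    return (not conflicts), conflicts


def pairs_to_frame(result: PairSearchResult) -> pd.DataFrame:
    """Tabulate ranked pairs (1-based template positions, Tm to 0.01 deg C)."""
    rows = []
    for p in result.pairs:
        rows.append(
            {
                "forward_seq": p.forward.sequence,
                "forward_start_1based": p.forward.template_start + 1,
                "forward_tm": round(p.forward.tm_c, 2),
                "reverse_seq": p.reverse.sequence,
                "reverse_start_1based": p.reverse.template_start + 1,
                "reverse_tm": round(p.reverse.tm_c, 2),
                "product_bp": p.product_bp,
                "tm_diff": round(p.tm_diff, 2),
                "score": round(p.score, 4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "forward_seq", "forward_start_1based", "forward_tm",
            "reverse_seq", "reverse_start_1based", "reverse_tm",
            "product_bp", "tm_diff", "score",
        ],
    )
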