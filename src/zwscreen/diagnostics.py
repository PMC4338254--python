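"""Species-diagnostic primer design and in-silico PCR.

Two closely related species are told apart by PCR when a primer's
3'-terminal base sits on an interspecies sequence difference: extension
proceeds on the matched (target) species and fails, or is strongly
disfavored, on the mismatched one.  This module aligns an ortholog pair,
lists the discriminating sites, enumerates primers that end 3' on a
difference and cover a minimum number of differences, ranks designs by
on-/off-target melting-temperature differential, and predicts amplicons by
scanning templates for productive primer binding-site pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .primers import DesignConstraints
from .thermo import melting_temperature, reverse_complement

__all__ = [
    "OrthologAlignment",
    "DiagnosticPrimer",
    "DiagnosticPair",
    "DiagnosticDesignResult",
    "Amplicon",
    "global_align",
    "discriminating_sites",
    "design_diagnostic_primers",
    "in_silico_pcr",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class OrthologAlignment:
    """A global alignment of two orthologous sequences ('-' for gaps)."""

    seq_a: str
    seq_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def difference_positions(self) -> list[int]:
        return [
            i
            for i, (a, b) in enumerate(zip(self.seq_a, self.seq_b))
            if a != "-" and b != "-" and a != b
        ]


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -12.0,
    gap_extend: float = -2.0,
) -> OrthologAlignment:
    """Needleman-Wunsch global alignment with affine gap penalties (Gotoh).

    A gap of length k costs ``gap_open + k * gap_extend`` (both negative).
    Traceback ties are broken deterministically: diagonal, then a gap in
    ``seq_b`` (consume from A), then a gap in ``seq_a``.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for s in (seq_a, seq_b):
        if set(s) - set("ACGT"):
            raise ValueError("sequences must be over ACGT")
    n, m = len(seq_a), len(seq_b)

    # M: last column aligned; X: gap in seq_b (A consumed); Y: gap in seq_a.
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == seq_b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open + gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open + gap_extend,
            )

    # traceback from the best terminal state, preferring M then X then Y
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda k: {"M": M, "X": X, "Y": Y}[k][n][m])
    score = {"M": M, "X": X, "Y": Y}[state][n][m]
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            s = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            prev = M[i][j] - s
            i, j = i - 1, j - 1
            for cand, table in (("M", M), ("X", X), ("Y", Y)):
                if abs(table[i][j] - prev) < 1e-9:
                    state = cand
                    break
        elif state == "X":
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            val = X[i][j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i][j] + gap_open + gap_extend - val) < 1e-9:
                state = "M"
            elif abs(X[i][j] + gap_extend - val) < 1e-9:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            val = Y[i][j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i][j] + gap_open + gap_extend - val) < 1e-9:
                state = "M"
            elif abs(Y[i][j] + gap_extend - val) < 1e-9:
                state = "Y"
            else:
                state = "X"
    return OrthologAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), score)


def discriminating_sites(alignment: OrthologAlignment) -> list[tuple[int, str, str]]:
    """Ungapped mismatch columns with both bases, sorted ascending."""
    return [
        (i, alignment.seq_a[i], alignment.seq_b[i])
        for i in alignment.difference_positions
    ]


@dataclass(frozen=True)
class DiagnosticPrimer:
    """An allele-/species-specific primer with its Tm differential.

    ``tm_on_target`` is the perfect-match Tm against the target species;
    ``tm_off_target`` the Tm of the same oligo against the other species
    (mismatch-destabilized); ``delta_tm`` their difference (always >= 0).
    """

    sequence: str
    strand: str  # '+' forward, '-' reverse
    window_start: int  # alignment column, 0-based, inclusive
    window_end: int
    three_prime_column: int
    covered_differences: tuple[int, ...]
    tm_on_target: float
    tm_off_target: float

    @property
    def n_differences_covered(self) -> int:
        return len(self.covered_differences)

    @property
    def three_prime_on_difference(self) -> bool:
        return self.three_prime_column in self.covered_differences

    @property
    def delta_tm(self) -> float:
        return self.tm_on_target - self.tm_off_target


@dataclass(frozen=True)
class DiagnosticPair:
    forward: DiagnosticPrimer
    reverse: DiagnosticPrimer

    @property
    def min_delta_tm(self) -> float:
        return min(self.forward.delta_tm, self.reverse.delta_tm)

    @property
    def total_differences(self) -> int:
        return self.forward.n_differences_covered + self.reverse.n_differences_covered


@dataclass
class DiagnosticDesignResult:
    status: str  # 'ok' or 'insufficient_divergence'
    primers: list[DiagnosticPrimer] = field(default_factory=list)
    pairs: list[DiagnosticPair] = field(default_factory=list)
    n_sites: int = 0


def design_diagnostic_primers(
    alignment: OrthologAlignment,
    target: str = "a",
    min_differences: int = 2,
    constraints: DesignConstraints | None = None,
) -> DiagnosticDesignResult:
    """Enumerate and rank species-discriminating primer pairs.

    Windows are gap-free stretches of the alignment, within the constraint
    length bounds, containing at least ``min_differences`` discriminating
    sites, with the 3'-terminal base on one of them (the leftmost covered
    site for reverse primers, the rightmost for forward primers).  Pairs are
    ranked by the smaller of the two primers' delta-Tm (descending), ties by
    total covered differences, then by position.
    """
    if target not in ("a", "b"):
        raise ValueError("target must be 'a' or 'b'")
    c = constraints or DesignConstraints()
    sites = [col for col, _, _ in discriminating_sites(alignment)]
    if len(sites) < max(min_differences, 2):
        return DiagnosticDesignResult("insufficient_divergence", n_sites=len(sites))
    site_set = set(sites)
    on_seq = alignment.seq_a if target == "a" else alignment.seq_b
    off_seq = alignment.seq_b if target == "a" else alignment.seq_a

    primers: list[DiagnosticPrimer] = []
    n_cols = len(on_seq)
    for anchor in sites:  # 3'-terminal column of the primer
        for length in range(c.primer_len_min, c.primer_len_max + 1):
            # forward primer: window ends at the anchor
            start = anchor - length + 1
            if start >= 0:
                p = _make_diag_primer(
                    on_seq, off_seq, start, anchor, "+", anchor, site_set, c
                )
                if p is not None and p.n_differences_covered >= min_differences:
                    primers.append(p)
            # reverse primer: window starts at the anchor
            end = anchor + length - 1
            if end < n_cols:
                p = _make_diag_primer(
                    on_seq, off_seq, anchor, end, "-", anchor, site_set, c
                )
                if p is not None and p.n_differences_covered >= min_differences:
                    primers.append(p)

    forwards = [p for p in primers if p.strand == "+"]
    reverses = [p for p in primers if p.strand == "-"]
    pairs = [
        DiagnosticPair(f, r)
        for f in forwards
        for r in reverses
        if r.window_start > f.window_end
    ]
    pairs.sort(
        key=lambda p: (
            -p.min_delta_tm,
            -p.total_differences,
            p.forward.window_start,
            p.reverse.window_start,
        )
    )
    return DiagnosticDesignResult("ok", primers=primers, pairs=pairs, n_sites=len(sites))


def _make_diag_primer(on_seq, off_seq, start, end, strand, anchor, site_set, c):
    on_win = on_seq[start : end + 1]
    off_win = off_seq[start : end + 1]
    if "-" in on_win or "-" in off_win:
        return None
    covered = tuple(col for col in range(start, end + 1) if col in site_set)
    if strand == "+":
        seq, ctx = on_win, off_win
    else:
        seq, ctx = reverse_complement(on_win), reverse_complement(off_win)
    tm_on = melting_temperature(seq, na_mM=c.na_mM, oligo_nM=c.oligo_nM)
    tm_off = melting_temperature(seq, ctx, na_mM=c.na_mM, oligo_nM=c.oligo_nM)
    return DiagnosticPrimer(
        sequence=seq,
        strand=strand,
        window_start=start,
        window_end=end,
        three_prime_column=anchor,
        covered_differences=covered,
        tm_on_target=tm_on,
        tm_off_target=tm_off,
    )


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product (1-based inclusive template coordinates)."""

    start_1based: int
    end_1based: int
    product_bp: int
    strand: str  # '+': the given forward primer sits on the plus strand


def _binding_sites(template, primer_plus, three_prime_at_start, max_mm, require_3p):
    """Positions where ``primer_plus`` (plus-strand spelling) binds.

    ``three_prime_at_start`` marks reverse-role primers whose 3' end maps to
    the leftmost covered template base.  Internal mismatches are counted
    against ``max_mm``; a 3'-terminal mismatch rejects the site when
    ``require_3p``.
    """
    L = len(primer_plus)
    sites = []
    for i in range(len(template) - L + 1):
        window = template[i : i + L]
        mm = sum(a != b for a, b in zip(window, primer_plus))
        three_idx = 0 if three_prime_at_start else L - 1
        mm_3p = window[three_idx] != primer_plus[three_idx]
        if require_3p and mm_3p:
            continue
        if mm - int(mm_3p) > max_mm:  # 3'-terminal base is not "internal"
            continue
        sites.append(i)
    return sites


def in_silico_pcr(
    template: str,
    forward: str,
    reverse: str,
    max_internal_mismatches: int = 2,
    require_3prime_match: bool = True,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    Both strands are scanned: the forward primer may bind the plus strand
    with the reverse primer binding the minus strand downstream ('+'
    products), or vice versa ('-' products).  The product is the inclusive
    5'-to-5' span.  Binding requires at most ``max_internal_mismatches``
    non-3'-terminal mismatches and (by default, as in allele-specific PCR) a
    perfectly matched 3'-terminal base.
    """
    if min(len(forward), len(reverse)) < 12:
        raise ValueError("primers must be at least 12 nt")
    if len(template) < len(forward) + len(reverse):
        raise ValueError("template shorter than the two primers combined")
    template = template.upper()
    products: list[Amplicon] = []
    for strand, fwd, rev in (("+", forward, reverse), ("-", reverse, forward)):
        f_sites = _binding_sites(
            template, fwd, False, max_internal_mismatches, require_3prime_match
        )
        r_sites = _binding_sites(
            template,
            reverse_complement(rev),
            True,
            max_internal_mismatches,
            require_3prime_match,
        )
        for i in f_sites:
            for j in r_sites:
                if j < i + len(fwd):
                    continue
                end = j + len(rev) - 1
                products.append(Amplicon(i + 1, end + 1, end - i + 1, strand))
    products.sort(key=lambda a: (a.start_1based, a.end_1based, a.strand))
    return products
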