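"""Nearest-neighbor DNA duplex thermodynamics.

Melting temperatures use the unified nearest-neighbor parameter set
(Allawi & SantaLucia stacking enthalpies/entropies with terminal initiation
terms), the two-state formula ``Tm(K) = dH / (dS + R ln(C_T/4))`` for
non-self-complementary oligos, and the logarithmic monovalent-salt
correction ``+16.6 log10([Na+])``.

Mismatched duplexes (a primer bound to an imperfect template) are handled
by a destabilization floor rather than a mismatch-parameterized NN table:
any stack containing a mismatched position contributes zero dH and dS, each
mismatched position is additionally charged a fixed destabilization penalty
(+2 kcal/mol of dH, no dS), and the two terminal initiation terms always
apply (the helix still has two ends).  The penalty term is what makes a
mismatch *strictly* lower the modeled Tm: removing a stack alone can
marginally raise the two-state Tm when the stack's dH/dS ratio lies below
the duplex melting point (A+T-rich stacks in warm duplexes).  The model is
deliberately conservative — sufficient for ranking allele-specific primers
by on-/off-target Tm differential — and documented as replaceable.
"""

from __future__ import annotations

import math

__all__ = ["melting_temperature", "duplex_dh_ds", "reverse_complement", "GAS_CONSTANT"]

#: cal / (mol K)
GAS_CONSTANT = 1.987

# Unified NN stacking parameters, keyed by the 5'->3' dinucleotide on the
# primer strand: (dH kcal/mol, dS cal/(mol K)).
NN_TABLE = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

# Duplex initiation per terminal base pair.
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

#: dH (kcal/mol) charged per mismatched position, on top of stack zeroing.
MISMATCH_PENALTY_DH = 2.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate(seq: str, min_len: int = 8) -> None:
    if len(seq) < min_len:
        raise ValueError(f"sequence too short for a duplex model (< {min_len} nt)")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT character(s) {sorted(bad)} in sequence")


def duplex_dh_ds(sequence: str, bound_context: str | None = None) -> tuple[float, float]:
    """Summed (dH kcal/mol, dS cal/mol/K) of the primer-template duplex.

    ``bound_context`` is the template window written in primer orientation
    (i.e. equal to ``sequence`` for a perfect match); positions where it
    differs from the primer are mismatches: every stack touching a
    mismatched position is zeroed and each mismatch is charged
    ``MISMATCH_PENALTY_DH``.  Initiation terms are charged at both ends
    regardless of the terminal match state.
    """
    _validate(sequence)
    if bound_context is None:
        bound_context = sequence
    if len(bound_context) != len(sequence):
        raise ValueError("bound_context must align position-by-position with sequence")
    matched = [a == b for a, b in zip(sequence, bound_context)]

    dh = ds = 0.0
    for i in range(len(sequence) - 1):
        if matched[i] and matched[i + 1]:
            h, s = NN_TABLE[sequence[i : i + 2]]
            dh += h
            ds += s
    dh += MISMATCH_PENALTY_DH * (len(matched) - sum(matched))
    for end in (0, -1):
        h, s = INIT_GC if sequence[end] in "GC" else INIT_AT
        dh += h
        ds += s
    return dh, ds


def melting_temperature(
    sequence: str,
    bound_context: str | None = None,
    na_mM: float = 50.0,
    oligo_nM: float = 500.0,
) -> float:
    """Duplex melting temperature in deg C.

    Two-state model with total strand concentration ``oligo_nM`` (C_T/4
    symmetry factor, non-self-complementary assumption) and the logarithmic
    Na+ correction.  A fully destabilized duplex (non-negative dH) is floored
    at 0 deg C rather than reporting a meaningless pole of the formula.
    """
    if na_mM <= 0 or oligo_nM <= 0:
        raise ValueError("salt and oligo concentrations must be positive")
    dh, ds = duplex_dh_ds(sequence, bound_context)
    if dh >= 0:
        return 0.0
    c_t = oligo_nM * 1e-9
    tm_k = (dh * 1000.0) / (ds + GAS_CONSTANT * math.log(c_t / 4.0))
    tm_c = tm_k - 273.15 + 16.6 * math.log10(na_mM / 1000.0)
    return max(0.0, tm_c)
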