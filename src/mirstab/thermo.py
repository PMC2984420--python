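"""Thermodynamic and composition features of pre-miRNA hairpins.

The central quantity is the adjusted minimum free energy

    AMFE = -MFE / length x 100   [kcal/mol per 100 nt]

which normalises folding free energies to a common sequence length so that
hairpins of different sizes can be compared; larger AMFE = more stable.

Also here: base-pairing fractions (bp %, (A-U) %), nucleotide composition,
a deliberately small nearest-neighbour structure-energy evaluator used by
the synthetic generator, and a Nussinov maximum-pairing routine with an
exhaustive-enumeration oracle for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from mirstab.elements import PairTable, build_pair_table
from mirstab.errors import ValidationError
from mirstab.records import PreMiRNARecord

#: canonical pairs (Watson-Crick) plus the G-U wobble, as unordered base sets
WATSON_CRICK = (frozenset("AU"), frozenset("GC"))
WOBBLE = frozenset("GU")
VALID_PAIRS = WATSON_CRICK + (WOBBLE,)

# ---------------------------------------------------------------------------
# Simplified nearest-neighbour energy model
# ---------------------------------------------------------------------------
# Per-pair strengths in kcal/mol, reflecting 3 vs 2 hydrogen bonds plus the
# weak wobble.  A stack of two adjacent pairs contributes minus the mean of
# their strengths; loops add fixed positive penalties.  The model's only
# contracts are determinism and monotonicity (stronger pairs => lower
# energy); it is NOT a substitute for a full Turner-parameter fold and its
# absolute values are not comparable to RNAfold output.
PAIR_STRENGTH = {
    frozenset("GC"): 3.2,
    frozenset("AU"): 1.1,
    frozenset("GU"): 0.5,
}

#: fixed energetic penalties, kcal/mol
HAIRPIN_LOOP_PENALTY = 4.0
INTERIOR_LOOP_PENALTY = 1.2   # per interior loop / bulge occurrence
INTERIOR_LOOP_PER_NT = 0.3    # per unpaired nucleotide in such loops


@dataclass(frozen=True)
class ThermoFeatures:
    """Stability and composition features of one record.

    Percentages are on a 0-100 scale; ``amfe`` is kcal/mol per 100 nt
    (positive for a stable fold).
    """

    id: str
    length: int
    mfe: float
    amfe: float
    bp_pct: float
    au_pair_pct: float
    a_pct: float
    u_pct: float
    g_pct: float
    c_pct: float

    @property
    def au_content_pct(self) -> float:
        return self.a_pct + self.u_pct


def compute_amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: -MFE / length x 100 (kcal/mol per 100 nt)."""
    if length <= 0:
        raise ValidationError(f"sequence length must be positive, got {length}")
    return -mfe / length * 100.0


def pair_type(base_i: str, base_j: str) -> frozenset:
    """The unordered base set of a pair; raises for non-canonical pairs."""
    pt = frozenset((base_i, base_j))
    if pt not in VALID_PAIRS:
        raise ValidationError(f"invalid base pair {base_i}-{base_j}")
    return pt


def pairing_features(sequence: str, pairs: PairTable) -> tuple[float, float]:
    """(bp %, (A-U) %) for one structure.

    bp % is the percentage of nucleotides engaged in base pairs; (A-U) % is
    the percentage of base pairs that are strict A-U pairs.  G-U wobbles
    count toward bp % but not toward the (A-U) % numerator.
    """
    n = len(sequence)
    if len(pairs) != n:
        raise ValidationError("pair table length does not match sequence")
    pair_list = pairs.pairs()
    if not pair_list:
        raise ValidationError("structure has no base pairs; (A-U) % is undefined")
    au = 0
    for i, j in pair_list:
        if pair_type(sequence[i - 1], sequence[j - 1]) == frozenset("AU"):
            au += 1
    bp_pct = 100.0 * 2 * len(pair_list) / n
    au_pair_pct = 100.0 * au / len(pair_list)
    return bp_pct, au_pair_pct


def nucleotide_composition(sequence: str) -> dict[str, float]:
    """Percent A, U, G, C and A+U over the sequence length."""
    if not sequence:
        raise ValidationError("empty sequence")
    n = len(sequence)
    comp = {b: 100.0 * sequence.count(b) / n for b in "AUGC"}
    comp["AU"] = comp["A"] + comp["U"]
    return comp


def compute_features(record: PreMiRNARecord) -> ThermoFeatures:
    """All thermodynamic/composition features for one record.

    Requires a parsed energy and at least one base pair.
    """
    if record.mfe is None:
        raise ValidationError(f"record {record.id!r} has no folding energy")
    pt = build_pair_table(record.dotbracket)
    bp_pct, au_pair_pct = pairing_features(record.sequence, pt)
    comp = nucleotide_composition(record.sequence)
    return ThermoFeatures(
        id=record.id,
        length=len(record),
        mfe=record.mfe,
        amfe=compute_amfe(record.mfe, len(record)),
        bp_pct=bp_pct,
        au_pair_pct=au_pair_pct,
        a_pct=comp["A"],
        u_pct=comp["U"],
        g_pct=comp["G"],
        c_pct=comp["C"],
    )


def features_frame(features: Iterable[ThermoFeatures]) -> pd.DataFrame:
    rows = [
        {
            "id": f.id,
            "length": f.length,
            "mfe": f.mfe,
            "amfe": f.amfe,
            "bp_pct": f.bp_pct,
            "au_pair_pct": f.au_pair_pct,
            "A_pct": f.a_pct,
            "U_pct": f.u_pct,
            "G_pct": f.g_pct,
            "C_pct": f.c_pct,
            "AU_pct": f.au_content_pct,
        }
        for f in features
    ]
    return pd.DataFrame(rows)


def write_features_table(features: Iterable[ThermoFeatures], path: str | Path) -> None:
    features_frame(features).to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Structure-energy evaluator (synthetic-data support)
# ---------------------------------------------------------------------------

def stack_energy(pair_a: frozenset, pair_b: frozenset) -> float:
    """Stacking term for two adjacent pairs: minus the mean pair strength."""
    return -(PAIR_STRENGTH[pair_a] + PAIR_STRENGTH[pair_b]) / 2.0


def evaluate_structure_energy(sequence: str, pairs: PairTable) -> float:
    """Deterministic free-energy estimate, kcal/mol, for a nested structure.

    Sum of stacking terms over every pair stacked directly on another pair,
    plus a fixed penalty per hairpin loop and a size-dependent penalty per
    interior loop / bulge.  An all-unpaired structure scores exactly 0.
    """
    n = len(sequence)
    if len(pairs) != n:
        raise ValidationError("pair table length does not match sequence")
    pair_list = pairs.pairs()
    if not pair_list:
        return 0.0
    for i, j in pair_list:
        pair_type(sequence[i - 1], sequence[j - 1])  # validates

    energy = 0.0
    for i, j in pair_list:
        if pairs.partner[i + 1] == j - 1 and j - 1 > i + 1:
            energy += stack_energy(
                pair_type(sequence[i - 1], sequence[j - 1]),
                pair_type(sequence[i], sequence[j - 2]),
            )

    # loop penalties: classify each pair's enclosed gap up to the next helix
    for i, j in pair_list:
        inner = [k for k in range(i + 1, j) if pairs.partner[k] != 0]
        if not inner:
            energy += HAIRPIN_LOOP_PENALTY
        elif pairs.partner[i + 1] != j - 1:
            # unpaired nucleotides between this pair and the next helix inward
            k5 = inner[0] - (i + 1)
            k3 = (j - 1) - inner[-1]
            if k5 + k3 > 0:
                energy += INTERIOR_LOOP_PENALTY + INTERIOR_LOOP_PER_NT * (k5 + k3)
    return energy


# ---------------------------------------------------------------------------
# Nussinov maximum pairing + exhaustive oracle
# ---------------------------------------------------------------------------

def _can_pair(a: str, b: str) -> bool:
    return frozenset((a, b)) in VALID_PAIRS


def nussinov_max_pairs(sequence: str, min_loop: int = 3) -> tuple[int, PairTable]:
    """Maximum number of nested pairs and one optimal pair table.

    Pairs are Watson-Crick or G-U, with at least ``min_loop`` unpaired
    nucleotides inside every hairpin loop.  Standard O(n^3) dynamic
    programme with traceback.
    """
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValidationError(f"non-RNA characters {sorted(bad)}")
    n = len(seq)
    best = [[0] * (n + 1) for _ in range(n + 2)]  # best[i][j], 1-based, i>j -> 0
    for span in range(2, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            score = best[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(seq[i - 1], seq[k - 1]):
                    inner = best[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    right = best[k + 1][j] if k + 1 <= j else 0
                    score = max(score, inner + right + 1)
            best[i][j] = score

    partner = [0] * (n + 1)

    def traceback(i: int, j: int) -> None:
        while i < j:
            if best[i][j] == best[i + 1][j]:
                i += 1
                continue
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(seq[i - 1], seq[k - 1]):
                    inner = best[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    right = best[k + 1][j] if k + 1 <= j else 0
                    if best[i][j] == inner + right + 1:
                        partner[i] = k
                        partner[k] = i
                        traceback(i + 1, k - 1)
                        i, j = k + 1, j
                        break
            else:  # pragma: no cover - DP/traceback mismatch cannot happen
                raise AssertionError("traceback failed")

    if n:
        traceback(1, n)
    return best[1][n] if n else 0, PairTable(tuple(partner))


MAX_ENUMERATION_LENGTH = 16


def enumerate_max_pairs(sequence: str, min_loop: int = 3) -> int:
    """Exhaustive maximum pair count over all nested structures.

    Independent brute-force oracle for :func:`nussinov_max_pairs`;
    restricted to sequences of length <= 16.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if n > MAX_ENUMERATION_LENGTH:
        raise ValidationError(
            f"exhaustive enumeration limited to length {MAX_ENUMERATION_LENGTH}"
        )

    def rec(positions: tuple[int, ...]) -> int:
        if not positions:
            return 0
        i = positions[0]
        rest = positions[1:]
        best_count = rec(rest)  # i unpaired
        for idx, k in enumerate(rest):
            if k - i - 1 >= min_loop and _can_pair(seq[i - 1], seq[k - 1]):
                inside = tuple(p for p in rest[:idx] if i < p < k)
                outside = tuple(p for p in rest[idx + 1:] if p > k)
                best_count = max(best_count, 1 + rec(inside) + rec(outside))
        return best_count

    return rec(tuple(range(1, n + 1)))
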