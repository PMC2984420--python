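"""Hairpin structural-element decomposition.

A hairpin secondary structure is partitioned into five element kinds:

* ``overhang``      -- unpaired single-stranded ends outside the outermost pair;
* ``first_stem``    -- the basal helix: the maximal run of stacked pairs that
  contains the outermost pair;
* ``interior_loop`` -- all unpaired nucleotides between helices (internal
  loops and bulges pooled, both strands counted);
* ``interior_stem`` -- every paired nucleotide not in the first stem;
* ``terminal_loop`` -- the unpaired run closed by the innermost pair.

Structures with zero pairs or with more than one hairpin loop (multibranch)
are rejected as non-hairpin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from mirstab.errors import NonHairpinError, ParseError, ValidationError

ELEMENT_KINDS = ("overhang", "first_stem", "interior_loop", "interior_stem", "terminal_loop")

#: element kinds whose U content is reported (overhangs are too short to
#: carry a meaningful U ratio and are skipped by convention)
U_RATIO_KINDS = ("first_stem", "interior_stem", "interior_loop", "terminal_loop")


@dataclass(frozen=True)
class PairTable:
    """Validated base-pair mapping for one structure.

    ``partner[i]`` is the 1-based partner of 1-based position ``i``, or 0
    when unpaired.  Index 0 is a sentinel.
    """

    partner: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.partner) - 1
        for i in range(1, n + 1):
            j = self.partner[i]
            if j == 0:
                continue
            if not 1 <= j <= n or j == i:
                raise ValidationError(f"pair table: invalid partner {j} for position {i}")
            if self.partner[j] != i:
                raise ValidationError(f"pair table: asymmetric pair ({i}, {j})")

    def __len__(self) -> int:
        return len(self.partner) - 1

    @property
    def n_pairs(self) -> int:
        return sum(1 for p in self.partner[1:] if p != 0) // 2

    def is_paired(self, i: int) -> bool:
        return self.partner[i] != 0

    def pairs(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, in 5'->3' order of i."""
        return [
            (i, self.partner[i])
            for i in range(1, len(self.partner))
            if self.partner[i] > i
        ]

    def paired_span(self) -> tuple[int, int] | None:
        """1-based interval from the 5'-most to the 3'-most paired base."""
        paired = [i for i in range(1, len(self.partner)) if self.partner[i] != 0]
        if not paired:
            return None
        return paired[0], paired[-1]


def build_pair_table(dotbracket: str) -> PairTable:
    """Stack-based matching of a balanced dot-bracket string."""
    n = len(dotbracket)
    partner = [0] * (n + 1)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced dot-bracket: unmatched ')' at position {i}")
            j = stack.pop()
            partner[j] = i
            partner[i] = j
        elif ch != ".":
            raise ParseError(f"illegal structure character {ch!r} at position {i}")
    if stack:
        raise ParseError(
            f"unbalanced dot-bracket: unmatched '(' at position {stack[0]}"
        )
    return PairTable(tuple(partner))


@dataclass
class ElementDecomposition:
    """Partition of all sequence positions into the five element kinds."""

    positions: dict[str, frozenset[int]]
    length: int

    def __post_init__(self) -> None:
        all_pos: set[int] = set()
        total = 0
        for kind in ELEMENT_KINDS:
            pos = self.positions.get(kind, frozenset())
            all_pos |= pos
            total += len(pos)
        if total != self.length or all_pos != set(range(1, self.length + 1)):
            raise ValidationError("element decomposition does not partition the sequence")

    def element_length(self, kind: str) -> int:
        return len(self.positions.get(kind, frozenset()))

    def lengths(self) -> dict[str, int]:
        return {kind: self.element_length(kind) for kind in ELEMENT_KINDS}


def count_hairpin_loops(pt: PairTable) -> int:
    """Number of pairs enclosing only unpaired bases (= number of hairpin loops)."""
    count = 0
    for i, j in pt.pairs():
        if all(pt.partner[k] == 0 for k in range(i + 1, j)):
            count += 1
    return count


def decompose_hairpin(pt: PairTable) -> ElementDecomposition:
    """Decompose a single-hairpin structure into the five element kinds.

    Raises :class:`NonHairpinError` for pair-free or multibranch structures;
    such records are disregarded from downstream analysis.
    """
    n = len(pt)
    if pt.n_pairs == 0:
        raise NonHairpinError("structure has no base pairs")
    n_loops = count_hairpin_loops(pt)
    if n_loops != 1:
        raise NonHairpinError(
            f"structure has {n_loops} hairpin loops; a hairpin must have exactly 1"
        )

    span = pt.paired_span()
    assert span is not None
    lo, hi = span
    if pt.partner[lo] != hi:
        # with exactly one hairpin loop all pairs are nested in one chain,
        # so the outermost paired bases must pair with each other
        raise NonHairpinError("outermost paired bases do not pair with each other")

    overhang = frozenset(range(1, lo)) | frozenset(range(hi + 1, n + 1))

    # first stem: maximal run of stacked pairs from the outermost pair inward
    first_stem: set[int] = set()
    i, j = lo, hi
    while pt.partner[i] == j:
        first_stem.add(i)
        first_stem.add(j)
        i, j = i + 1, j - 1

    # terminal loop: unpaired run inside the innermost pair
    terminal_loop: set[int] = set()
    for a, b in pt.pairs():
        if all(pt.partner[k] == 0 for k in range(a + 1, b)):
            terminal_loop = set(range(a + 1, b))
            break

    paired = {k for k in range(1, n + 1) if pt.partner[k] != 0}
    interior_stem = paired - first_stem
    interior_loop = (
        set(range(lo, hi + 1)) - paired - terminal_loop
    )

    return ElementDecomposition(
        positions={
            "overhang": frozenset(overhang),
            "first_stem": frozenset(first_stem),
            "interior_loop": frozenset(interior_loop),
            "interior_stem": frozenset(interior_stem),
            "terminal_loop": frozenset(terminal_loop),
        },
        length=n,
    )


def element_metrics(
    sequence: str, decomp: ElementDecomposition
) -> dict[str, dict[str, float | None]]:
    """Per-element length ratios and U ratios.

    Returns ``{kind: {"length": int, "length_ratio": float, "u_ratio": x}}``
    where ``u_ratio`` is U count / element length for the four stem/loop
    kinds, and ``None`` for empty elements and for overhangs.
    """
    n = decomp.length
    if len(sequence) != n:
        raise ValidationError("sequence length does not match decomposition")
    out: dict[str, dict[str, float | None]] = {}
    for kind in ELEMENT_KINDS:
        pos = decomp.positions.get(kind, frozenset())
        length = len(pos)
        u_ratio: float | None = None
        if kind in U_RATIO_KINDS and length > 0:
            u_count = sum(1 for p in pos if sequence[p - 1] == "U")
            u_ratio = u_count / length
        out[kind] = {
            "length": length,
            "length_ratio": length / n,
            "u_ratio": u_ratio,
        }
    return out


def write_element_table(
    rows: Iterable[tuple[str, ElementDecomposition, dict[str, dict[str, float | None]]]],
    path: str | Path,
) -> None:
    """Write per-record element metrics as TSV (empty u_ratio when undefined).

    ``start``/``end`` are the 1-based extremes of the element's positions;
    pooled kinds (interior loops, overhangs) may be non-contiguous, in which
    case the interval merely brackets them.
    """
    with open(path, "w") as fh:
        fh.write("id\tkind\tstart\tend\tlength\tlength_ratio\tu_ratio\n")
        for rec_id, decomp, metrics in rows:
            for kind in ELEMENT_KINDS:
                m = metrics[kind]
                pos = decomp.positions.get(kind, frozenset())
                start = str(min(pos)) if pos else ""
                end = str(max(pos)) if pos else ""
                u = "" if m["u_ratio"] is None else f"{m['u_ratio']:.4f}"
                fh.write(
                    f"{rec_id}\t{kind}\t{start}\t{end}\t{int(m['length'])}\t"
                    f"{m['length_ratio']:.4f}\t{u}\n"
                )
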