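"""Dual-constraint conservation classification of pre-miRNAs.

A record is *window-conserved* when some 15-nt window of its per-nucleotide
conservation scores, lying entirely within the hairpin stem region, has an
arithmetic-mean score of at least 0.9.  The stem region defaults to the
full contiguous span between the outermost paired bases (``"span"`` mode);
``"paired"`` mode restricts windows to the subsequence of paired positions.

The window flag is then combined with the family's phylogenetic breadth M
(the number of taxonomic families in which the miRNA family occurs):

===================  ==========  =========
window conserved     M           group
===================  ==========  =========
no                   1           S_n (non-conserved)
no                   > 1         excluded
yes                  < 5         excluded
yes                  5-9         S_c1
yes                  10-19       S_c2
yes                  >= 20       S_c3
===================  ==========  =========

Finally, any (species, group) set with fewer than ``min_set_size`` members
is dropped from comparisons (members flagged, not deleted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from mirstab.elements import PairTable
from mirstab.errors import ValidationError

logger = logging.getLogger(__name__)

GROUPS = ("S_n", "S_c1", "S_c2", "S_c3")
CONSERVED_GROUPS = ("S_c1", "S_c2", "S_c3")

DEFAULT_WINDOW = 15
DEFAULT_THRESHOLD = 0.9
DEFAULT_MIN_SET_SIZE = 5


@dataclass(frozen=True)
class ConservationLabel:
    """Group assignment with its provenance."""

    group: str  # S_n | S_c1 | S_c2 | S_c3 | excluded
    window_conserved: bool
    m_value: int | None
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS + ("excluded",):
            raise ValidationError(f"unknown conservation group {self.group!r}")


def stem_region(pairs: PairTable, mode: str = "span") -> Sequence[int]:
    """1-based positions constituting the hairpin stem region.

    ``"span"``: every position from the 5'-most to the 3'-most paired base
    (loops inside the span included).  ``"paired"``: paired positions only.
    """
    span = pairs.paired_span()
    if span is None:
        return ()
    lo, hi = span
    if mode == "span":
        return range(lo, hi + 1)
    if mode == "paired":
        return tuple(i for i in range(lo, hi + 1) if pairs.is_paired(i))
    raise ValidationError(f"unknown stem region mode {mode!r}")


def window_conserved(
    scores: Sequence[float],
    stem_positions: Sequence[int],
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
) -> bool:
    """True iff some ``window``-length run of stem positions has mean >= threshold.

    Windows slide by one position over the stem region; the threshold
    comparison is inclusive ("no smaller than").  A stem region shorter
    than the window cannot satisfy the rule (logged, returns False).
    """
    stem_positions = list(stem_positions)
    if len(stem_positions) < window:
        logger.warning(
            "stem region of %d nt is shorter than the %d-nt window; "
            "record cannot be window-conserved",
            len(stem_positions),
            window,
        )
        return False
    vals = np.asarray([scores[p - 1] for p in stem_positions], dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValidationError("conservation scores outside [0, 1]")
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    # guard the inclusive boundary against float accumulation error
    return bool(np.any(means >= threshold - 1e-12))


def assign_conservation_group(
    is_window_conserved: bool, m_value: int | None
) -> ConservationLabel:
    """Combine the window flag with family breadth M into a group label."""
    if m_value is None:
        return ConservationLabel(
            "excluded", is_window_conserved, None, exclusion_reason="no family data"
        )
    if m_value < 1:
        raise ValidationError(f"m_value must be >= 1, got {m_value}")
    if not is_window_conserved:
        if m_value == 1:
            return ConservationLabel("S_n", False, m_value)
        return ConservationLabel(
            "excluded", False, m_value,
            exclusion_reason=f"non-conserved but family has homologs (M={m_value} > 1)",
        )
    if m_value < 5:
        return ConservationLabel(
            "excluded", True, m_value,
            exclusion_reason=f"window-conserved but few homologs (M={m_value} < 5)",
        )
    if m_value <= 9:
        return ConservationLabel("S_c1", True, m_value)
    if m_value <= 19:
        return ConservationLabel("S_c2", True, m_value)
    return ConservationLabel("S_c3", True, m_value)


def filter_study_population(
    labels: Mapping[str, Mapping[str, str]],
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> dict[str, dict[str, str]]:
    """Drop undersized (species, group) sets from the comparison population.

    ``labels`` maps species -> {record id -> group}.  Returns the same
    nesting with members of dropped sets re-labelled
    ``"dropped:<group>"`` so they remain visible but leave comparisons.
    """
    out: dict[str, dict[str, str]] = {}
    for species, by_id in labels.items():
        counts: dict[str, int] = {}
        for group in by_id.values():
            counts[group] = counts.get(group, 0) + 1
        dropped = {
            g for g, c in counts.items()
            if g in GROUPS and c < min_set_size
        }
        for g in sorted(dropped):
            logger.info(
                "species %s: set %s dropped (%d < %d members)",
                species, g, counts[g], min_set_size,
            )
        out[species] = {
            rid: (f"dropped:{g}" if g in dropped else g)
            for rid, g in by_id.items()
        }
    return out


def write_labels_table(
    rows: Iterable[tuple[str, str, ConservationLabel]], path: str | Path
) -> None:
    """Write (id, species, label) rows as the labels TSV."""
    with open(path, "w") as fh:
        fh.write("id\tspecies\twindow_conserved\tm_value\tgroup\texclusion_reason\n")
        for rec_id, species, lab in rows:
            m = "" if lab.m_value is None else str(lab.m_value)
            reason = lab.exclusion_reason or ""
            fh.write(
                f"{rec_id}\t{species}\t{int(lab.window_conserved)}\t{m}\t"
                f"{lab.group}\t{reason}\n"
            )
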