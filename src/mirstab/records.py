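"""Record types and readers/writers for all external file formats.

Formats handled here:

* Vienna-style records -- a ``>id [species]`` header line, a sequence line,
  and a dot-bracket line with the folding free energy in trailing
  parentheses, as printed by RNAfold (e.g. ``((((....)))) (-12.30)``).
* Plain FASTA for sequences without structure.
* Per-nucleotide conservation tracks as TSV: either long form
  ``id <TAB> pos <TAB> score`` (1-based positions) or bedGraph-like
  ``id <TAB> start <TAB> end <TAB> score`` (1-based, inclusive).
* Family tables as TSV with columns ``id``, ``family_id``, ``m_value``
  where ``m_value`` is the number of taxonomic families in which the
  miRNA family occurs (phylogenetic breadth, M).

All coordinates at every file interface are 1-based and inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from mirstab.errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase, map T to U, and reject anything outside {A,C,G,U}.

    Ambiguity codes (N, R, Y, ...) are rejected rather than guessed at.
    """
    seq = raw.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValidationError(
            f"record {record_id!r}: sequence contains non-RNA characters "
            f"{sorted(bad)} (ambiguity codes are not supported)"
        )
    return seq


def check_balanced(dotbracket: str, record_id: str = "?") -> None:
    """Raise :class:`ParseError` unless the dot-bracket string is balanced.

    Balanced means equal counts of '(' and ')' with no prefix in which
    ')' outnumber '('.  The error names the first offending index (1-based).
    """
    depth = 0
    open_at = []
    for i, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            depth += 1
            open_at.append(i)
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(
                    f"record {record_id!r}: unbalanced dot-bracket, "
                    f"unmatched ')' at position {i}"
                )
            open_at.pop()
        elif ch != ".":
            raise ParseError(
                f"record {record_id!r}: illegal structure character {ch!r} "
                f"at position {i}"
            )
    if depth != 0:
        raise ParseError(
            f"record {record_id!r}: unbalanced dot-bracket, "
            f"unmatched '(' at position {open_at[0]}"
        )


@dataclass
class PreMiRNARecord:
    """One pre-miRNA: sequence, structure, energy and annotation.

    Attributes
    ----------
    id : str
        Record identifier (e.g. ``hsa-mir-21``).
    sequence : str
        RNA sequence over {A,C,G,U}; T is mapped to U on construction.
    dotbracket : str
        Secondary structure in dot-bracket notation, same length as
        ``sequence`` and balanced.
    mfe : float or None
        Minimum free energy of the fold in kcal/mol (<= 0 by convention
        for a folded structure); ``None`` when the input carried no energy.
    species : str
        Free-text species tag ("" when unknown).
    conservation : list of float or None
        Per-nucleotide conservation scores in [0, 1], one per base.
    family_id : str or None
        miRNA family identifier.
    m_value : int or None
        Phylogenetic breadth M of the family (>= 1).
    """

    id: str
    sequence: str
    dotbracket: str
    mfe: float | None = None
    species: str = ""
    conservation: list[float] | None = None
    family_id: str | None = None
    m_value: int | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, self.id)
        check_balanced(self.dotbracket, self.id)
        if len(self.sequence) != len(self.dotbracket):
            raise ValidationError(
                f"record {self.id!r}: sequence length {len(self.sequence)} "
                f"!= structure length {len(self.dotbracket)}"
            )
        if self.conservation is not None:
            self._check_conservation(self.conservation)
        if self.m_value is not None and self.m_value < 1:
            raise ValidationError(f"record {self.id!r}: m_value must be >= 1")

    def _check_conservation(self, scores: list[float]) -> None:
        if len(scores) != len(self.sequence):
            raise ValidationError(
                f"record {self.id!r}: {len(scores)} conservation scores for "
                f"{len(self.sequence)} nucleotides"
            )
        for pos, s in enumerate(scores, start=1):
            if not 0.0 <= s <= 1.0:
                raise ValidationError(
                    f"record {self.id!r}: conservation score {s} at position "
                    f"{pos} outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_conservation(self, scores: Iterable[float]) -> "PreMiRNARecord":
        """Return a copy carrying the given per-nucleotide score track."""
        return replace(self, conservation=list(scores))

    def with_family(self, family_id: str, m_value: int) -> "PreMiRNARecord":
        return replace(self, family_id=family_id, m_value=int(m_value))


@dataclass
class FamilyTable:
    """Mapping pre-miRNA id -> (family_id, M value)."""

    entries: dict[str, tuple[str, int]] = field(default_factory=dict)

    def add(self, record_id: str, family_id: str, m_value: int) -> None:
        if record_id in self.entries:
            raise ValidationError(f"duplicate id {record_id!r} in family table")
        m = int(m_value)
        if m != m_value or m < 1:
            raise ValidationError(
                f"record {record_id!r}: m_value must be an integer >= 1, got {m_value!r}"
            )
        self.entries[record_id] = (str(family_id), m)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def family_of(self, record_id: str) -> str:
        return self.entries[record_id][0]

    def m_of(self, record_id: str) -> int:
        return self.entries[record_id][1]

    def annotate(self, records: Iterable[PreMiRNARecord]) -> list[PreMiRNARecord]:
        """Attach family_id / m_value to every record present in the table."""
        out = []
        for rec in records:
            if rec.id in self.entries:
                fam, m = self.entries[rec.id]
                out.append(rec.with_family(fam, m))
            else:
                out.append(rec)
        return out


# ---------------------------------------------------------------------------
# Vienna-style records
# ---------------------------------------------------------------------------

def read_vienna(path: str | Path) -> list[PreMiRNARecord]:
    """Read RNAfold-style records: header, sequence, structure+energy.

    Records missing the trailing ``(energy)`` are accepted with
    ``mfe=None`` and a logged warning; structural errors are fatal.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    records: list[PreMiRNARecord] = []
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ParseError(f"{path}: expected '>' header at line {i + 1}, got {header!r}")
        if i + 2 >= len(lines):
            raise ParseError(f"{path}: truncated record {header!r}")
        tokens = header[1:].split()
        if not tokens:
            raise ParseError(f"{path}: empty header at line {i + 1}")
        rec_id = tokens[0]
        species = tokens[1] if len(tokens) > 1 else ""
        seq_line = lines[i + 1].strip()
        struct_line = lines[i + 2].strip()
        m = _ENERGY_RE.search(struct_line)
        if m:
            mfe: float | None = float(m.group(1))
            dotbracket = struct_line[: m.start()].strip()
        else:
            mfe = None
            dotbracket = struct_line
            logger.warning("record %r: no folding energy on structure line", rec_id)
        records.append(
            PreMiRNARecord(
                id=rec_id,
                species=species,
                sequence=seq_line,
                dotbracket=dotbracket,
                mfe=mfe,
            )
        )
        i += 3
    return records


def write_vienna(records: Iterable[PreMiRNARecord], path: str | Path) -> None:
    """Write records in the same three-line format :func:`read_vienna` reads.

    Energies are printed with two decimals, matching RNAfold output.
    """
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.species:
                header += f" {rec.species}"
            fh.write(header + "\n")
            fh.write(rec.sequence + "\n")
            if rec.mfe is None:
                fh.write(rec.dotbracket + "\n")
            else:
                fh.write(f"{rec.dotbracket} ({rec.mfe:.2f})\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read plain FASTA into an ordered ``{id: sequence}`` mapping."""
    seqs: dict[str, str] = {}
    cur_id: str | None = None
    chunks: list[str] = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith(">"):
            if cur_id is not None:
                seqs[cur_id] = normalize_sequence("".join(chunks), cur_id)
            cur_id = ln[1:].split()[0]
            if cur_id in seqs:
                raise ParseError(f"{path}: duplicate FASTA id {cur_id!r}")
            chunks = []
        else:
            chunks.append(ln)
    if cur_id is not None:
        seqs[cur_id] = normalize_sequence("".join(chunks), cur_id)
    return seqs


# ---------------------------------------------------------------------------
# Conservation tracks
# ---------------------------------------------------------------------------

def read_conservation_track(
    path: str | Path,
    lengths: Mapping[str, int],
) -> dict[str, list[float]]:
    """Read a per-nucleotide score track and return ``{id: scores}``.

    ``lengths`` gives the expected sequence length per record id; rows for
    unknown ids are skipped with a logged warning.  Two layouts are
    auto-detected by column count: long form ``id pos score`` and
    bedGraph-like ``id start end score`` (both 1-based, end inclusive).

    Scores outside [0, 1] and position gaps are hard errors -- scores are
    never clipped.
    """
    per_record: dict[str, dict[int, float]] = {}
    skipped: set[str] = set()
    with open(Path(path)) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            fields = ln.split("\t") if "\t" in ln else ln.split()
            if fields[0] in ("id", "track"):  # header line
                continue
            if len(fields) == 3:
                rec_id, pos_s, score_s = fields
                start = end = int(pos_s)
            elif len(fields) == 4:
                rec_id, start_s, end_s, score_s = fields
                start, end = int(start_s), int(end_s)
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
                )
            if rec_id not in lengths:
                if rec_id not in skipped:
                    logger.warning(
                        "conservation track: unknown id %r, rows skipped", rec_id
                    )
                    skipped.add(rec_id)
                continue
            score = float(score_s)
            if not 0.0 <= score <= 1.0:
                raise ParseError(
                    f"{path}:{lineno}: record {rec_id!r} score {score} outside [0, 1]"
                )
            bucket = per_record.setdefault(rec_id, {})
            for pos in range(start, end + 1):
                if not 1 <= pos <= lengths[rec_id]:
                    raise ParseError(
                        f"{path}:{lineno}: record {rec_id!r} position {pos} outside "
                        f"1..{lengths[rec_id]}"
                    )
                bucket[pos] = score

    tracks: dict[str, list[float]] = {}
    for rec_id, scores in per_record.items():
        n = lengths[rec_id]
        missing = [p for p in range(1, n + 1) if p not in scores]
        if missing:
            shown = ", ".join(map(str, missing[:10]))
            more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
            raise ParseError(
                f"record {rec_id!r}: conservation track has gaps at positions "
                f"{shown}{more}"
            )
        tracks[rec_id] = [scores[p] for p in range(1, n + 1)]
    return tracks


def write_conservation_track(tracks: Mapping[str, list[float]], path: str | Path) -> None:
    """Write tracks in long form (id, pos, score) with a header line."""
    with open(path, "w") as fh:
        fh.write("id\tpos\tscore\n")
        for rec_id, scores in tracks.items():
            for pos, s in enumerate(scores, start=1):
                fh.write(f"{rec_id}\t{pos}\t{s:.4f}\n")


def attach_conservation(
    records: list[PreMiRNARecord], tracks: Mapping[str, list[float]]
) -> list[PreMiRNARecord]:
    """Return records with their score tracks attached where available."""
    return [
        rec.with_conservation(tracks[rec.id]) if rec.id in tracks else rec
        for rec in records
    ]


# ---------------------------------------------------------------------------
# Family tables
# ---------------------------------------------------------------------------

def read_family_table(path: str | Path) -> FamilyTable:
    """Read a TSV with columns id, family_id, m_value (header optional)."""
    table = FamilyTable()
    with open(Path(path)) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            fields = ln.split("\t") if "\t" in ln else ln.split()
            if lineno == 1 and fields[0] == "id":
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 columns (id, family_id, m_value)"
                )
            rec_id, family_id, m_s = fields
            try:
                m_float = float(m_s)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: m_value {m_s!r} is not a number"
                ) from exc
            if m_float != int(m_float):
                raise ValidationError(
                    f"{path}:{lineno}: m_value {m_s!r} is not an integer"
                )
            table.add(rec_id, family_id, int(m_float))
    return table


def write_family_table(table: FamilyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tfamily_id\tm_value\n")
        for rec_id, (family_id, m) in table.entries.items():
            fh.write(f"{rec_id}\t{family_id}\t{m}\n")
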