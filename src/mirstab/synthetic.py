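"""Synthetic pre-miRNA populations with exact ground truth.

The generator is structure-first: element sizes (overhangs, basal helix,
interior helices and loops, terminal loop) are sampled first and the
dot-bracket string is assembled from them, so the true element
decomposition, pairing statistics and conservation labels of every record
are known exactly by construction.  Sequence-first generation followed by
folding is deliberately avoided.

Conservation tracks are planted: records meant to be conserved carry a
block of >= 15 consecutive scores >= 0.92 inside the hairpin stem span,
records meant to be non-conserved have every score <= 0.85, so the 15-nt
window rule recovers the planted labels with no stochastic leakage.

Reproducibility: one global seed drives a hierarchical
``numpy.random.SeedSequence`` stream, one child per record, so individual
records are reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from mirstab.elements import ELEMENT_KINDS, build_pair_table, decompose_hairpin
from mirstab.errors import ValidationError
from mirstab.records import (
    FamilyTable,
    PreMiRNARecord,
    write_conservation_track,
    write_family_table,
    write_vienna,
)
from mirstab.thermo import compute_amfe, evaluate_structure_energy

#: default M-value sampling ranges per conservation group
DEFAULT_M_RANGES = {
    "S_n": (1, 1),
    "S_c1": (5, 9),
    "S_c2": (10, 19),
    "S_c3": (20, 30),
}

#: unpaired-base weights (A, U, G, C); conserved pre-miRNAs are U-enriched
UNPAIRED_WEIGHTS_NONCONSERVED = (0.22, 0.26, 0.27, 0.25)
UNPAIRED_WEIGHTS_CONSERVED = (0.23, 0.31, 0.25, 0.21)


@dataclass(frozen=True)
class StructureParams:
    """Inclusive size ranges for the sampled hairpin elements (nt or bp)."""

    overhang_nt: tuple[int, int] = (0, 5)          # per side
    first_stem_bp: tuple[int, int] = (4, 10)
    n_interior_segments: tuple[int, int] = (1, 3)
    interior_stem_bp: tuple[int, int] = (3, 8)
    interior_loop_side_nt: tuple[int, int] = (0, 3)  # per side; 0/0 resampled
    terminal_loop_nt: tuple[int, int] = (3, 9)

    def __post_init__(self) -> None:
        if self.terminal_loop_nt[0] < 3:
            raise ValidationError("a hairpin loop needs at least 3 unpaired nt")
        for name in ("overhang_nt", "first_stem_bp", "n_interior_segments",
                     "interior_stem_bp", "interior_loop_side_nt", "terminal_loop_nt"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValidationError(f"bad range for {name}: ({lo}, {hi})")
        if self.first_stem_bp[0] < 1:
            raise ValidationError("first stem needs at least 1 bp")


@dataclass(frozen=True)
class GroupSpec:
    """One (species, group) cell of the synthetic population.

    ``amfe_mean``/``amfe_sd`` (kcal/mol per 100 nt), when set, specify the
    group's AMFE distribution directly (normal, truncated at 5); otherwise
    the record keeps the structure-derived nearest-neighbour energy.
    """

    n: int
    group: str
    window_conserved: bool | None = None   # default: True for S_c*, False for S_n
    m_range: tuple[int, int] | None = None
    amfe_mean: float | None = None
    amfe_sd: float | None = None
    gc_pair_weight: float = 0.45
    au_pair_weight: float = 0.45
    unpaired_weights: tuple[float, float, float, float] | None = None

    def resolved(self) -> "GroupSpec":
        conserved = self.group.startswith("S_c")
        out = self
        if out.window_conserved is None:
            out = replace(out, window_conserved=conserved)
        if out.m_range is None:
            if self.group not in DEFAULT_M_RANGES:
                raise ValidationError(
                    f"group {self.group!r} has no default M range; set m_range"
                )
            out = replace(out, m_range=DEFAULT_M_RANGES[self.group])
        if out.unpaired_weights is None:
            w = UNPAIRED_WEIGHTS_CONSERVED if conserved else UNPAIRED_WEIGHTS_NONCONSERVED
            out = replace(out, unpaired_weights=w)
        if not 0 <= out.gc_pair_weight + out.au_pair_weight <= 1:
            raise ValidationError("pair weights must sum to at most 1")
        if abs(sum(out.unpaired_weights) - 1.0) > 1e-9:
            raise ValidationError("unpaired weights must sum to 1")
        return out


@dataclass
class SyntheticSpec:
    """Full specification of a synthetic multi-species population."""

    populations: dict[str, dict[str, GroupSpec]]  # species -> group name -> spec
    structure: StructureParams = field(default_factory=StructureParams)
    conserved_block_score: tuple[float, float] = (0.92, 1.0)
    conserved_background: tuple[float, float] = (0.2, 0.7)
    nonconserved_score: tuple[float, float] = (0.0, 0.85)
    seed: int = 0


@dataclass
class SyntheticRecord:
    """A generated record together with its exact ground truth."""

    record: PreMiRNARecord
    species: str
    true_group: str
    true_window_conserved: bool
    element_lengths: dict[str, int]


@dataclass
class Population:
    records: list[SyntheticRecord]
    family_table: FamilyTable

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for sr in self.records:
            row = {
                "id": sr.record.id,
                "species": sr.species,
                "group": sr.true_group,
                "window_conserved": sr.true_window_conserved,
                "m_value": sr.record.m_value,
                "length": len(sr.record),
                "amfe": compute_amfe(sr.record.mfe, len(sr.record)),
            }
            for kind in ELEMENT_KINDS:
                row[f"len_{kind}"] = sr.element_lengths[kind]
            rows.append(row)
        return pd.DataFrame(rows)


def _randint(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def sample_structure(
    params: StructureParams, rng: np.random.Generator
) -> tuple[str, dict[str, int]]:
    """Sample a hairpin dot-bracket; returns it with true element lengths."""
    o5 = _randint(rng, params.overhang_nt)
    o3 = _randint(rng, params.overhang_nt)
    k1 = _randint(rng, params.first_stem_bp)
    n_seg = _randint(rng, params.n_interior_segments)
    segments = []
    for _ in range(n_seg):
        while True:
            l5 = _randint(rng, params.interior_loop_side_nt)
            l3 = _randint(rng, params.interior_loop_side_nt)
            if l5 + l3 > 0:
                break
        bp = _randint(rng, params.interior_stem_bp)
        segments.append((l5, bp, l3))
    loop = _randint(rng, params.terminal_loop_nt)

    five = "." * o5 + "(" * k1
    three = ")" * k1 + "." * o3
    for l5, bp, l3 in segments:
        five += "." * l5 + "(" * bp
        three = ")" * bp + "." * l3 + three
    db = five + "." * loop + three

    lengths = {
        "overhang": o5 + o3,
        "first_stem": 2 * k1,
        "interior_stem": 2 * sum(bp for _, bp, _ in segments),
        "interior_loop": sum(l5 + l3 for l5, _, l3 in segments),
        "terminal_loop": loop,
    }
    return db, lengths


_PAIR_CHOICES = {
    "GC": ("G", "C"),
    "AU": ("A", "U"),
    "GU": ("G", "U"),
}


def fill_sequence(dotbracket: str, gspec: GroupSpec, rng: np.random.Generator) -> str:
    """Sample nucleotides compatible with the structure.

    Paired positions draw a pair class (G-C / A-U / G-U wobble) by the
    group's weights with uniform orientation; unpaired positions draw from
    the group's composition weights.
    """
    pt = build_pair_table(dotbracket)
    bases = [""] * len(dotbracket)
    p_gc, p_au = gspec.gc_pair_weight, gspec.au_pair_weight
    for i, j in pt.pairs():
        u = rng.random()
        kind = "GC" if u < p_gc else ("AU" if u < p_gc + p_au else "GU")
        a, b = _PAIR_CHOICES[kind]
        if rng.random() < 0.5:
            a, b = b, a
        bases[i - 1], bases[j - 1] = a, b
    unpaired_idx = [k for k in range(len(dotbracket)) if pt.partner[k + 1] == 0]
    draws = rng.choice(4, size=len(unpaired_idx), p=gspec.unpaired_weights)
    for k, d in zip(unpaired_idx, draws):
        bases[k] = "AUGC"[d]
    return "".join(bases)


def plant_conservation(
    dotbracket: str,
    conserved: bool,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    window: int = 15,
) -> list[float]:
    """Per-nucleotide scores with the planted window-rule outcome."""
    n = len(dotbracket)
    pt = build_pair_table(dotbracket)
    span = pt.paired_span()
    if not conserved:
        lo, hi = spec.nonconserved_score
        return list(rng.uniform(lo, hi, size=n))
    if span is None or span[1] - span[0] + 1 < window:
        raise ValidationError(
            "stem span shorter than the conservation window; cannot plant a block"
        )
    lo, hi = spec.conserved_background
    scores = rng.uniform(lo, hi, size=n)
    span_lo, span_hi = span
    max_block = span_hi - span_lo + 1
    block_len = int(rng.integers(window, min(max_block, window + 10) + 1))
    start = int(rng.integers(span_lo, span_hi - block_len + 2))
    blo, bhi = spec.conserved_block_score
    scores[start - 1 : start - 1 + block_len] = rng.uniform(blo, bhi, size=block_len)
    return list(scores)


def generate_hairpin(
    rec_id: str,
    species: str,
    gspec: GroupSpec,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> SyntheticRecord:
    """One synthetic record with exact ground truth."""
    gspec = gspec.resolved()
    db, lengths = sample_structure(spec.structure, rng)
    seq = fill_sequence(db, gspec, rng)
    pt = build_pair_table(db)
    mfe = evaluate_structure_energy(seq, pt)
    if gspec.amfe_mean is not None:
        sd = gspec.amfe_sd if gspec.amfe_sd is not None else 0.0
        amfe = max(5.0, rng.normal(gspec.amfe_mean, sd))
        mfe = -amfe * len(seq) / 100.0
    scores = plant_conservation(db, bool(gspec.window_conserved), spec, rng)
    m_value = _randint(rng, gspec.m_range)
    record = PreMiRNARecord(
        id=rec_id,
        species=species,
        sequence=seq,
        dotbracket=db,
        mfe=round(mfe, 2),
        conservation=scores,
        family_id=f"fam-{rec_id}",
        m_value=m_value,
    )
    # generated structures are guaranteed single hairpins; verify anyway
    computed = decompose_hairpin(pt).lengths()
    if computed != lengths:  # pragma: no cover - construction defect
        raise AssertionError(f"ground-truth mismatch for {rec_id}")
    return SyntheticRecord(
        record=record,
        species=species,
        true_group=gspec.group,
        true_window_conserved=bool(gspec.window_conserved),
        element_lengths=lengths,
    )


def generate_population(spec: SyntheticSpec) -> Population:
    """Generate the full multi-species population described by ``spec``."""
    root = np.random.SeedSequence(spec.seed)
    records: list[SyntheticRecord] = []
    family = FamilyTable()
    cells = [
        (species, gname, gspec)
        for species, groups in sorted(spec.populations.items())
        for gname, gspec in sorted(groups.items())
    ]
    total = sum(g.n for _, _, g in cells)
    children: Iterator[np.random.SeedSequence] = iter(root.spawn(total))
    for species, gname, gspec in cells:
        for k in range(gspec.n):
            rng = np.random.default_rng(next(children))
            rec_id = f"{species}-{gname}-{k:04d}"
            sr = generate_hairpin(rec_id, species, gspec, spec, rng)
            records.append(sr)
            family.add(rec_id, sr.record.family_id, sr.record.m_value)
    return Population(records=records, family_table=family)


def emit_population(pop: Population, out_dir: str | Path) -> dict[str, Path]:
    """Write the population in the same formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.vienna",
        "conservation": out / "conservation.tsv",
        "families": out / "families.tsv",
        "truth": out / "truth.tsv",
    }
    write_vienna([sr.record for sr in pop.records], paths["records"])
    write_conservation_track(
        {sr.record.id: sr.record.conservation for sr in pop.records},
        paths["conservation"],
    )
    write_family_table(pop.family_table, paths["families"])
    pop.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: (n, AMFE mean, AMFE sd) per species and group for the "table1-like"
#: preset, mirroring the observed study-population sizes and AMFE
#: distributions; chicken S_c1 is deliberately undersized (4 < 5) to
#: exercise the minimum-set-size drop rule.
TABLE1_LIKE_CELLS: dict[str, dict[str, tuple[int, float, float]]] = {
    "human": {
        "S_n": (132, 44.1, 14.1),
        "S_c1": (60, 45.2, 9.98),
        "S_c2": (66, 44.6, 7.06),
        "S_c3": (33, 44.7, 6.36),
    },
    "mouse": {
        "S_n": (108, 41.0, 9.79),
        "S_c1": (63, 45.1, 7.83),
        "S_c2": (75, 45.0, 6.93),
        "S_c3": (39, 43.8, 5.89),
    },
    "chicken": {
        "S_n": (21, 42.2, 14.7),
        "S_c1": (4, 43.0, 8.0),
        "S_c2": (40, 41.6, 5.59),
        "S_c3": (19, 42.3, 5.05),
    },
}


def table1_like_spec(seed: int = 0) -> SyntheticSpec:
    """Population with group sizes and AMFE distributions like the three
    real study populations; non-conserved sets get wider AMFE spread and
    lower A-U pair weight, conserved sets U-enriched composition."""
    populations: dict[str, dict[str, GroupSpec]] = {}
    for species, cells in TABLE1_LIKE_CELLS.items():
        populations[species] = {}
        for gname, (n, mean, sd) in cells.items():
            conserved = gname.startswith("S_c")
            populations[species][gname] = GroupSpec(
                n=n,
                group=gname,
                amfe_mean=mean,
                amfe_sd=sd,
                gc_pair_weight=0.42 if conserved else 0.50,
                au_pair_weight=0.50 if conserved else 0.42,
            )
    return SyntheticSpec(populations=populations, seed=seed)


def null_spec(seed: int = 0, n_per_group: int = 60) -> SyntheticSpec:
    """No group differences: identical AMFE and composition distributions
    in every set; only conservation tracks and M values differ."""
    populations: dict[str, dict[str, GroupSpec]] = {"synth": {}}
    for gname in ("S_n", "S_c1", "S_c2", "S_c3"):
        populations["synth"][gname] = GroupSpec(
            n=n_per_group,
            group=gname,
            amfe_mean=44.0,
            amfe_sd=8.0,
            gc_pair_weight=0.45,
            au_pair_weight=0.45,
            unpaired_weights=(0.25, 0.25, 0.25, 0.25),
        )
    return SyntheticSpec(populations=populations, seed=seed)


PRESETS = {"table1-like": table1_like_spec, "null": null_spec}


def load_spec(path: str | Path) -> SyntheticSpec:
    """Load a SyntheticSpec from a YAML configuration file.

    Schema::

        seed: 1
        structure: {first_stem_bp: [4, 10], ...}   # optional overrides
        populations:
          human:
            S_n:  {n: 50, amfe_mean: 44.0, amfe_sd: 12.0}
            S_c3: {n: 20, amfe_mean: 44.0, amfe_sd: 6.0}
    """
    cfg = yaml.safe_load(Path(path).read_text())
    structure = StructureParams(
        **{k: tuple(v) for k, v in cfg.get("structure", {}).items()}
    )
    populations: dict[str, dict[str, GroupSpec]] = {}
    for species, groups in cfg["populations"].items():
        populations[species] = {}
        for gname, params in groups.items():
            params = dict(params)
            if "m_range" in params:
                params["m_range"] = tuple(params["m_range"])
            if "unpaired_weights" in params:
                params["unpaired_weights"] = tuple(params["unpaired_weights"])
            populations[species][gname] = GroupSpec(group=gname, **params)
    return SyntheticSpec(
        populations=populations,
        structure=structure,
        seed=int(cfg.get("seed", 0)),
    )
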