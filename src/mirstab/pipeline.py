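"""End-to-end orchestration: features -> elements -> conservation -> statistics.

The pipeline consumes either real inputs (Vienna records, a conservation
track, a family table) or a synthetic population, and writes a report
bundle: feature, element, label, extreme-stability and partition TSVs,
group summary/comparison tables, pooled means, and a JSON run manifest
itemising parameters and the record counts at every filter step
(non-hairpin disregards, M-rule exclusions, set-size drops).  Identical
configuration and seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from mirstab import __version__
from mirstab.conservation import (
    ConservationLabel,
    assign_conservation_group,
    filter_study_population,
    stem_region,
    window_conserved,
    write_labels_table,
)
from mirstab.elements import (
    build_pair_table,
    decompose_hairpin,
    element_metrics,
    write_element_table,
)
from mirstab.errors import MirstabError, NonHairpinError, ValidationError
from mirstab.records import (
    PreMiRNARecord,
    attach_conservation,
    read_conservation_track,
    read_family_table,
    read_vienna,
)
from mirstab.stats import (
    classify_extreme_stability,
    partition_by_thresholds,
    summarize_and_compare,
    write_partition_table,
    write_report_tables,
)
from mirstab.thermo import compute_features, features_frame
from mirstab.synthetic import PRESETS, emit_population, generate_population, load_spec

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline inputs and stage parameters.

    Exactly one of (``records_path``) or (``synthetic_preset`` /
    ``synthetic_spec_path``) must be set.
    """

    out_dir: str | Path = "mirstab-out"
    records_path: str | Path | None = None
    conservation_path: str | Path | None = None
    families_path: str | Path | None = None
    synthetic_preset: str | None = None
    synthetic_spec_path: str | Path | None = None
    window_length: int = 15
    score_threshold: float = 0.9
    stem_region_mode: str = "span"  # or "paired"
    min_set_size: int = 5
    quantile_mode: str = "linear"   # or "nearest"
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    seed: int = 0

    def validate(self) -> None:
        real = self.records_path is not None
        synth = self.synthetic_preset is not None or self.synthetic_spec_path is not None
        if real == synth:
            raise ValidationError(
                "exactly one of a records file or a synthetic preset/spec must be given"
            )
        if self.window_length < 1:
            raise ValidationError("window_length must be >= 1")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValidationError("score_threshold must lie in [0, 1]")
        if self.stem_region_mode not in ("span", "paired"):
            raise ValidationError(f"unknown stem_region_mode {self.stem_region_mode!r}")
        if self.quantile_mode not in ("linear", "nearest"):
            raise ValidationError(f"unknown quantile_mode {self.quantile_mode!r}")
        if real and self.conservation_path is None:
            raise ValidationError(
                "conservation classification requires a conservation track"
            )
        if real and self.families_path is None:
            raise ValidationError("conservation classification requires a family table")


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict = field(default_factory=dict)


def _load_records(config: PipelineConfig) -> list[PreMiRNARecord]:
    if config.records_path is not None:
        for p in (config.records_path, config.conservation_path, config.families_path):
            if p is not None and not Path(p).exists():
                raise MirstabError(f"input file not found: {p}")
        records = read_vienna(config.records_path)
        tracks = read_conservation_track(
            config.conservation_path, {r.id: len(r) for r in records}
        )
        records = attach_conservation(records, tracks)
        families = read_family_table(config.families_path)
        return families.annotate(records)
    if config.synthetic_spec_path is not None:
        spec = load_spec(config.synthetic_spec_path)
    else:
        if config.synthetic_preset not in PRESETS:
            raise ValidationError(
                f"unknown preset {config.synthetic_preset!r}; "
                f"available: {sorted(PRESETS)}"
            )
        spec = PRESETS[config.synthetic_preset](seed=config.seed)
    pop = generate_population(spec)
    emit_population(pop, Path(config.out_dir) / "synthetic")
    return [sr.record for sr in pop.records]


def _species_of(record: PreMiRNARecord) -> str:
    if record.species:
        return record.species
    # synthetic ids are "<species>-<group>-<k>"
    return record.id.split("-")[0] if "-" in record.id else "unknown"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = _load_records(config)
    n_input = len(records)

    # --- features + element decomposition; non-hairpins are disregarded ----
    analyzed: list[tuple[PreMiRNARecord, object, object]] = []
    disregarded: list[tuple[str, str]] = []
    for rec in records:
        if rec.mfe is None:
            disregarded.append((rec.id, "missing folding energy"))
            continue
        pt = build_pair_table(rec.dotbracket)
        try:
            decomp = decompose_hairpin(pt)
            feats = compute_features(rec)
        except NonHairpinError as exc:
            logger.warning("record %s disregarded: %s", rec.id, exc)
            disregarded.append((rec.id, str(exc)))
            continue
        analyzed.append((rec, pt, decomp, feats))

    features_df = features_frame([f for _, _, _, f in analyzed])
    features_df.to_csv(out / "features.tsv", sep="\t", index=False, float_format="%.4f")
    write_element_table(
        [
            (rec.id, decomp, element_metrics(rec.sequence, decomp))
            for rec, _, decomp, _ in analyzed
        ],
        out / "elements.tsv",
    )

    # --- conservation classification ---------------------------------------
    labels: list[tuple[str, str, ConservationLabel]] = []
    for rec, pt, _, _ in analyzed:
        if rec.conservation is None:
            raise MirstabError(
                f"record {rec.id} has no conservation track; classification impossible"
            )
        stem = stem_region(pt, config.stem_region_mode)
        wc = window_conserved(
            rec.conservation, stem,
            window=config.window_length, threshold=config.score_threshold,
        )
        labels.append((rec.id, _species_of(rec), assign_conservation_group(wc, rec.m_value)))
    write_labels_table(labels, out / "labels.tsv")
    excluded = [(rid, lab.exclusion_reason) for rid, _, lab in labels
                if lab.group == "excluded"]

    # --- set-size filtering -------------------------------------------------
    by_species: dict[str, dict[str, str]] = {}
    for rid, species, lab in labels:
        if lab.group != "excluded":
            by_species.setdefault(species, {})[rid] = lab.group
    filtered = filter_study_population(by_species, config.min_set_size)
    final_group = {rid: g for groups in filtered.values() for rid, g in groups.items()}
    dropped = [(rid, g) for rid, g in final_group.items() if g.startswith("dropped:")]

    # --- statistics ---------------------------------------------------------
    feat_by_id = {f.id: f for _, _, _, f in analyzed}
    species_by_id = {rid: sp for rid, sp, _ in labels}
    rows = []
    for rid, group in final_group.items():
        if group.startswith("dropped:"):
            continue
        f = feat_by_id[rid]
        rows.append(
            {"id": rid, "species": species_by_id[rid], "group": group,
             "amfe": f.amfe, "bp_pct": f.bp_pct, "au_pair_pct": f.au_pair_pct,
             "AU_pct": f.au_content_pct, "A_pct": f.a_pct, "U_pct": f.u_pct,
             "G_pct": f.g_pct, "C_pct": f.c_pct}
        )
    data = pd.DataFrame(rows)
    n_analyzed = len(data)

    extremes_rows = []
    partition = None
    if not data.empty:
        report = summarize_and_compare(
            data, alpha_levels=config.alpha_levels, min_set_size=config.min_set_size
        )
        write_report_tables(report, out)

        for species, sub in data.groupby("species"):
            ext = classify_extreme_stability(
                dict(zip(sub["id"], sub["amfe"])), config.quantile_mode
            )
            for rid in sub["id"]:
                label = (
                    "ultra_stable" if rid in ext.ultra
                    else "unstable" if rid in ext.unstable
                    else "moderate"
                )
                extremes_rows.append(
                    {"id": rid, "species": species, "stability": label,
                     "p10": ext.lower, "p90": ext.upper, "low_n": ext.low_n}
                )

        sc3 = data[data["group"] == "S_c3"]["amfe"]
        if not sc3.empty:
            partition = partition_by_thresholds(
                sc3.to_numpy(),
                {r["id"]: (r["group"], r["amfe"]) for r in rows},
                config.quantile_mode,
            )
            write_partition_table(partition, out / "partition.tsv")

    pd.DataFrame(
        extremes_rows,
        columns=["id", "species", "stability", "p10", "p90", "low_n"],
    ).to_csv(out / "extremes.tsv", sep="\t", index=False, float_format="%.4f")

    manifest = {
        "version": __version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "counts": {
            "input": n_input,
            "disregarded_non_hairpin": len(disregarded),
            "excluded_m_rules": len(excluded),
            "dropped_set_size": len(dropped),
            "analyzed": n_analyzed,
        },
        "disregarded": [{"id": rid, "reason": r} for rid, r in disregarded],
        "excluded": [{"id": rid, "reason": r} for rid, r in excluded],
        "dropped": [{"id": rid, "set": g.split(":", 1)[1]} for rid, g in dropped],
        "thresholds": (
            {"T1": partition.t1, "T2": partition.t2} if partition is not None else None
        ),
    }
    assert (
        manifest["counts"]["input"]
        == manifest["counts"]["analyzed"]
        + manifest["counts"]["disregarded_non_hairpin"]
        + manifest["counts"]["excluded_m_rules"]
        + manifest["counts"]["dropped_set_size"]
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(out_dir=out, manifest=manifest)
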