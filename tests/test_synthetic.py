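"""Synthetic population generator: determinism, ground truth, planting."""

import numpy as np
import pandas as pd
import pytest

from mirstab.conservation import assign_conservation_group, stem_region, window_conserved
from mirstab.elements import build_pair_table, decompose_hairpin
from mirstab.errors import ValidationError
from mirstab.records import read_vienna
from mirstab.stats import summarize_and_compare
from mirstab.synthetic import (
    GroupSpec,
    StructureParams,
    SyntheticSpec,
    emit_population,
    generate_hairpin,
    generate_population,
    load_spec,
    null_spec,
    table1_like_spec,
)
from mirstab.thermo import evaluate_structure_energy


def _single_group_spec(n=5, seed=0, **group_kwargs):
    kwargs = {"n": n, "group": "S_c3"} | group_kwargs
    return SyntheticSpec(
        populations={"synth": {kwargs["group"]: GroupSpec(**kwargs)}}, seed=seed
    )


def test_same_seed_same_population():
    a = generate_population(_single_group_spec(seed=11))
    b = generate_population(_single_group_spec(seed=11))
    for sa, sb in zip(a.records, b.records):
        assert sa.record == sb.record
    c = generate_population(_single_group_spec(seed=12))
    assert any(sa.record != sc.record for sa, sc in zip(a.records, c.records))


def test_ground_truth_decomposition_matches_computed(small_population):
    for sr in small_population.records:
        pt = build_pair_table(sr.record.dotbracket)
        assert decompose_hairpin(pt).lengths() == sr.element_lengths


def test_structure_params_validated():
    with pytest.raises(ValidationError):
        StructureParams(terminal_loop_nt=(2, 5))
    with pytest.raises(ValidationError):
        StructureParams(first_stem_bp=(5, 3))


def test_fixed_geometry_bp_pct():
    """A 20-bp perfect stem with an 8-nt loop gives bp % = 40/48 exactly."""
    spec = SyntheticSpec(
        populations={"synth": {"S_n": GroupSpec(n=3, group="S_n")}},
        structure=StructureParams(
            overhang_nt=(0, 0),
            first_stem_bp=(20, 20),
            n_interior_segments=(0, 0),
            terminal_loop_nt=(8, 8),
        ),
        seed=5,
    )
    pop = generate_population(spec)
    for sr in pop.records:
        assert len(sr.record) == 48
        pt = build_pair_table(sr.record.dotbracket)
        assert 100 * 2 * pt.n_pairs / len(sr.record) == pytest.approx(83.33, abs=0.01)


def test_gc_rich_groups_are_more_stable(rng):
    """Mean nearest-neighbour energy over 200 draws is strictly lower for
    GC-weight 0.9 than for GC-weight 0.1."""
    def mean_energy(gc_weight, seed):
        spec = _single_group_spec(
            n=200, seed=seed, gc_pair_weight=gc_weight,
            au_pair_weight=0.9 - gc_weight,
        )
        pop = generate_population(spec)
        return np.mean([
            evaluate_structure_energy(
                sr.record.sequence, build_pair_table(sr.record.dotbracket)
            )
            for sr in pop.records
        ])

    assert mean_energy(0.9, seed=21) < mean_energy(0.1, seed=21)


def test_planted_labels_recovered_exactly(small_population):
    """The window rule + M grouping recover every planted label: no
    stochastic leakage of conserved blocks into S_n records."""
    for sr in small_population.records:
        pt = build_pair_table(sr.record.dotbracket)
        wc = window_conserved(sr.record.conservation, stem_region(pt))
        assert wc == sr.true_window_conserved
        label = assign_conservation_group(wc, sr.record.m_value)
        assert label.group == sr.true_group


def test_amfe_targets_reached(table1_population):
    truth = table1_population.truth_frame()
    cell = truth[(truth.species == "human") & (truth.group == "S_n")]
    # n=132 draws from N(44.1, 14.1): mean within 3 standard errors
    assert cell["amfe"].mean() == pytest.approx(44.1, abs=3 * 14.1 / np.sqrt(132))


def test_composition_converges_to_group_weights():
    spec = _single_group_spec(n=150, seed=9, group="S_n",
                              unpaired_weights=(0.1, 0.6, 0.2, 0.1))
    pop = generate_population(spec)
    u_fracs = []
    for sr in pop.records:
        pt = build_pair_table(sr.record.dotbracket)
        unpaired = [sr.record.sequence[i - 1] for i in range(1, len(sr.record) + 1)
                    if not pt.is_paired(i)]
        u_fracs.append(unpaired.count("U") / len(unpaired))
    pooled = np.mean(u_fracs)
    se = np.std(u_fracs, ddof=1) / np.sqrt(len(u_fracs))
    assert abs(pooled - 0.6) < 3 * se + 0.01


def test_emitted_files_round_trip(tmp_path, small_population):
    paths = emit_population(small_population, tmp_path)
    records = read_vienna(paths["records"])
    assert len(records) == len(small_population.records)
    for rec, sr in zip(records, small_population.records):
        assert rec.sequence == sr.record.sequence
        assert rec.dotbracket == sr.record.dotbracket
        assert rec.mfe == pytest.approx(sr.record.mfe, abs=0.005)
    truth = pd.read_csv(paths["truth"], sep="\t")
    assert set(truth.columns) >= {"id", "species", "group", "amfe"}


def test_yaml_spec_loader(tmp_path):
    cfg = tmp_path / "spec.yaml"
    cfg.write_text(
        """
seed: 3
structure:
  first_stem_bp: [5, 8]
populations:
  human:
    S_n: {n: 4, amfe_mean: 44.0, amfe_sd: 10.0}
    S_c3: {n: 3, amfe_mean: 44.0, amfe_sd: 5.0, m_range: [25, 30]}
"""
    )
    spec = load_spec(cfg)
    assert spec.seed == 3
    assert spec.structure.first_stem_bp == (5, 8)
    pop = generate_population(spec)
    assert len(pop.records) == 7
    sc3_m = [sr.record.m_value for sr in pop.records if sr.true_group == "S_c3"]
    assert all(25 <= m <= 30 for m in sc3_m)


def test_null_population_false_positive_rate():
    """With identical group distributions the BH-adjusted significant-
    comparison rate stays near the nominal FDR level."""
    n_sig = 0
    n_cmp = 0
    for rep in range(40):
        pop = generate_population(null_spec(seed=1000 + rep, n_per_group=30))
        truth = pop.truth_frame()
        data = truth.rename(columns={})[["id", "species", "group", "amfe"]]
        report = summarize_and_compare(data, metrics=("amfe",))
        n_sig += int(report.comparisons["sig_mean_05"].sum())
        n_sig += int(report.comparisons["sig_var_05"].sum())
        n_cmp += 2 * len(report.comparisons)
    assert n_cmp == 40 * 6
    assert n_sig / n_cmp < 0.10
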