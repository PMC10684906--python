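"""Read filtering, binning, control normalization and copy-state calling."""

import numpy as np
import pandas as pd
import pytest

from karyoscreen.dosage import (
    AlignedReadPair,
    DosageProfile,
    DosageThresholds,
    ReadFilterStats,
    bin_reads,
    call_dosage,
    dosage_pipeline,
    filter_reads,
    normalize_dosage,
    read_alignments,
)
from karyoscreen.errors import GridMismatchError, KaryoscreenError
from karyoscreen.layout import BinGrid, GenomeLayout
from karyoscreen.simulate import (
    MUTANT_PARENT,
    WILDTYPE_PARENT,
    OffspringSpec,
    SimulationConfig,
    simulate_cross,
    write_alignments,
)

from conftest import oracle_sam_bin_counts, oracle_sam_retained


def _pair(flag=99, mapq=60, same=True, chrom="chr1", pos=1001, span=150):
    return AlignedReadPair(chrom, flag, mapq, same, pos, span)


@pytest.mark.parametrize(
    "record, kept",
    [
        (_pair(flag=99, mapq=60, same=True), True),
        (_pair(flag=83, mapq=60, same=True), True),
        (_pair(flag=147, mapq=60, same=True), True),
        (_pair(flag=163, mapq=60, same=True), True),
        (_pair(flag=99, mapq=30, same=True), False),  # non-unique mapping
        (_pair(flag=99, mapq=60, same=False), False),  # mate on another contig
        (_pair(flag=77, mapq=60, same=True), False),  # pair unmapped
        (_pair(flag=97, mapq=60, same=True), False),  # not a proper pair
    ],
)
def test_read_filter_clauses(record, kept):
    assert (list(filter_reads([record])) == [record]) is kept


def test_filter_preserves_order_and_tallies_reasons():
    records = [
        _pair(pos=10),
        _pair(flag=77),
        _pair(pos=20),
        _pair(mapq=0),
        _pair(same=False),
        _pair(pos=30),
    ]
    stats = ReadFilterStats()
    kept = list(filter_reads(records, stats))
    assert [r.pos for r in kept] == [10, 20, 30]
    assert stats.retained == 3
    assert stats.improper_flag == 1
    assert stats.non_unique_mapq == 1
    assert stats.bad_mate_contig == 1
    assert stats.discarded == 3


def test_filter_is_idempotent():
    records = [_pair(pos=p) for p in (10, 20)] + [_pair(flag=77)]
    once = list(filter_reads(records))
    assert list(filter_reads(once)) == once


@pytest.mark.parametrize(
    "pos, span, expected_bin",
    [
        (124_926, 150, 0),  # mid coordinate 125,000: interior of bin 0
        (249_926, 150, 1),  # mid coordinate 250,000: half-open -> bin 1
        (1, 150, 0),
    ],
)
def test_mid_position_bin_assignment(grid, pos, span, expected_bin):
    counts = bin_reads([_pair(pos=pos, span=span)], grid)
    assert counts["chr1"][expected_bin] == 1
    assert sum(c.sum() for c in counts.values()) == 1


def test_binning_unknown_contig_names_it(grid):
    with pytest.raises(KeyError, match="scaffold_12"):
        bin_reads([_pair(chrom="scaffold_12")], grid)


def test_bin_counts_equal_brute_force_recount(sim_dir, grid, layout):
    """Conservation: pysam-route counts equal the per-line oracle, bin by bin."""
    path = sim_dir / "aneuploid_mono7_000.sam"
    stats = ReadFilterStats()
    counts = bin_reads(filter_reads(read_alignments(path), stats), grid)
    expected = oracle_sam_bin_counts(path, grid.bin_size, layout.names)
    for chrom in layout.names:
        assert list(counts[chrom]) == expected[chrom]
    assert stats.retained == len(oracle_sam_retained(path))
    assert sum(int(c.sum()) for c in counts.values()) == stats.retained
    assert stats.discarded > 0  # the fixture plants decoys


def _flat_counts(grid, per_bin):
    return {c: np.full(grid.n_bins(c), per_bin, dtype=np.int64) for c in grid.chromosomes}


def test_normalization_definitional_values(grid):
    """Sample percent equal to control mean -> 2.0; half of it -> 1.0."""
    controls = [_flat_counts(grid, 100), _flat_counts(grid, 100)]
    equal = normalize_dosage(_flat_counts(grid, 100), controls, grid)
    assert np.allclose(equal.frame["normalized"], 2.0)
    # halve one chromosome only: its bins sit near 1, the rest above 2
    sample = _flat_counts(grid, 100)
    sample["chr7"] //= 2
    prof = normalize_dosage(sample, controls, grid)
    chr7 = prof.chromosome_values("chr7")
    total_ratio = 180 / 170  # denominator shrinks with the lost copies
    assert np.allclose(chr7, total_ratio)
    assert np.allclose(prof.chromosome_values("chr1"), 2 * total_ratio)


def test_percent_depth_sums_to_one(grid):
    controls = [_flat_counts(grid, 60), _flat_counts(grid, 80)]
    prof = normalize_dosage(_flat_counts(grid, 50), controls, grid)
    assert prof.frame["percent"].sum() == pytest.approx(1.0, abs=1e-9)


def test_normalization_requires_two_controls_and_matching_grid(grid):
    with pytest.raises(KaryoscreenError, match="2 control"):
        normalize_dosage(_flat_counts(grid, 10), [_flat_counts(grid, 10)], grid)
    small = BinGrid(GenomeLayout(("chr1",), {"chr1": 1_000_000}, 250_000))
    with pytest.raises(GridMismatchError):
        normalize_dosage(
            _flat_counts(small, 10), [_flat_counts(grid, 10), _flat_counts(grid, 10)], grid
        )


def test_zero_control_bins_are_masked_not_divided(grid):
    controls = [_flat_counts(grid, 100), _flat_counts(grid, 100)]
    for ctrl in controls:
        ctrl["chr3"][5] = 0
    prof = normalize_dosage(_flat_counts(grid, 100), controls, grid)
    chr3 = prof.chromosome_values("chr3")
    assert np.isnan(chr3[5])
    assert np.isfinite(np.delete(chr3, 5)).all()
    # masked bins keep their position: frame rows stay aligned to the grid
    assert len(prof.frame) == sum(grid.n_bins(c) for c in grid.chromosomes)


def test_normalized_values_invariant_to_uniform_coverage_scaling(grid):
    """Multiplying a sample's coverage by any c > 0 changes nothing."""
    rng = np.random.default_rng(2)
    sample = {c: rng.poisson(60, grid.n_bins(c)) for c in grid.chromosomes}
    controls = [
        {c: rng.poisson(60, grid.n_bins(c)) for c in grid.chromosomes} for _ in range(4)
    ]
    base = normalize_dosage(sample, controls, grid)
    scaled = normalize_dosage({c: 7 * v for c, v in sample.items()}, controls, grid)
    assert np.allclose(base.frame["normalized"], scaled.frame["normalized"], equal_nan=True)


def test_controls_self_normalize_to_diploid(sim_dir, grid, control_sams):
    """Each control vs the control set: genome-wide median within [1.9, 2.1]."""
    for path in control_sams:
        profile, call, _ = dosage_pipeline(path, control_sams, grid, sample_id=path.stem)
        assert 1.9 <= profile.genome_median() <= 2.1
        assert all(state == "disomic" for state in call.states.values())


def test_whole_genome_duplication_is_invisible(sim_dir, grid, control_sams):
    """Relative-only contract: a tetraploid profiles exactly like a diploid."""
    profile, call, _ = dosage_pipeline(
        sim_dir / "eliminated_tetraploid_000.sam", control_sams, grid, "tetraploid"
    )
    assert 1.9 <= profile.genome_median() <= 2.1
    assert all(state == "disomic" for state in call.states.values())
    assert call.segments == []


def _profile_from_values(grid, values_by_chrom):
    rows = []
    for chrom in grid.chromosomes:
        for b, v in enumerate(values_by_chrom[chrom]):
            rows.append(
                {"chrom": chrom, "bin_start": b * grid.bin_size,
                 "bin_end": (b + 1) * grid.bin_size, "raw": 0, "percent": 0.0,
                 "normalized": v}
            )
    return DosageProfile("synthetic", pd.DataFrame(rows))


def test_call_dosage_states_and_segments(grid):
    values = {c: np.full(20, 2.0) for c in grid.chromosomes}
    values["chr7"] = np.full(20, 1.0)
    values["chr9"] = np.concatenate([np.full(10, 2.0), np.full(10, 2.6)])
    call = call_dosage(_profile_from_values(grid, values))
    assert call.states["chr7"] == "monosomic"
    assert call.states["chr9"] == "disomic"
    assert all(call.states[c] == "disomic" for c in grid.chromosomes if c not in ("chr7", "chr9"))
    (seg,) = call.segments
    assert (seg["chrom"], seg["start_bin"], seg["end_bin"]) == ("chr9", 10, 20)
    assert seg["mean_normalized"] == pytest.approx(2.6)


def test_call_dosage_null_case_and_short_runs(grid):
    values = {c: np.full(20, 2.0) for c in grid.chromosomes}
    values["chr2"][3:8] = 2.6  # 5 deviating bins < min_run_bins=8: not reported
    call = call_dosage(_profile_from_values(grid, values))
    assert call.segments == []
    assert set(call.states.values()) == {"disomic"}


def test_all_masked_chromosome_flagged_other(grid):
    values = {c: np.full(20, 2.0) for c in grid.chromosomes}
    values["chr5"] = np.full(20, np.nan)
    call = call_dosage(_profile_from_values(grid, values))
    assert call.states["chr5"] == "other"
    assert call.uninformative == ["chr5"]


@pytest.mark.parametrize("median, state", [
    (1.0, "monosomic"), (1.49, "monosomic"), (1.5, "disomic"), (2.49, "disomic"),
    (2.5, "trisomic"), (3.49, "trisomic"), (3.5, "other"),
])
def test_state_thresholds(grid, median, state):
    values = {c: np.full(20, 2.0) for c in grid.chromosomes}
    values["chr1"] = np.full(20, median)
    t = DosageThresholds(segment_deviation=10.0)  # silence segment reporting
    assert call_dosage(_profile_from_values(grid, values), t).states["chr1"] == state


def test_karyotype_recovery_across_simulated_classes(tmp_path, layout, grid):
    """Diploid, monosomic-7 and segmental 3-copy karyotypes are recovered
    from seeded simulations at depth 60 per bin-copy, 20 runs in all."""
    trisomy_9 = ("chr9", 10, 19, 3)  # 9 bins: median still disomic
    for run in range(20):
        karyotype = ("diploid", "mono7", "seg3")[run % 3]
        cfg = SimulationConfig(seed=300 + run, depth_per_copy=60.0)
        _, _, offs = simulate_cross(layout, cfg, {"f1": 5, "aneuploid_mono7": 1})
        controls = [o for o in offs if o.class_label == "f1"][:4]
        if karyotype == "diploid":
            sample = [o for o in offs if o.class_label == "f1"][4]
        elif karyotype == "mono7":
            sample = [o for o in offs if o.class_label == "aneuploid_mono7"][0]
        else:
            f1 = [o for o in offs if o.class_label == "f1"][4]
            sample = OffspringSpec(
                "seg3", "f1", f1.origins, "het", 2, segment_overrides=(trisomy_9,)
            )
        paths = []
        for o in controls:
            p = tmp_path / f"{run}_{o.offspring_id}.sam"
            write_alignments(o, layout, cfg, p)
            paths.append(p)
        sp = tmp_path / f"{run}_sample.sam"
        write_alignments(sample, layout, cfg, sp)
        _, call, _ = dosage_pipeline(sp, paths, grid, karyotype)
        if karyotype == "mono7":
            assert call.states["chr7"] == "monosomic"
            assert all(call.states[c] == "disomic" for c in layout.names if c != "chr7")
        else:
            assert all(v == "disomic" for v in call.states.values())
        if karyotype == "seg3":
            assert any(
                s["chrom"] == "chr9"
                and min(s["end_bin"], 19) - max(s["start_bin"], 10) >= 8
                and 2.5 <= s["mean_normalized"] <= 3.5
                for s in call.segments
            )
        elif karyotype == "diploid":
            assert call.segments == []
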