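"""Shared fixtures: one simulated cross, written to disk once per session,
plus independent line-by-line oracle parsers for SAM and VCF used to
cross-check the pysam-based pipeline counts."""

from __future__ import annotations

from pathlib import Path

import pytest

from karyoscreen.layout import BinGrid, GenomeLayout
from karyoscreen.simulate import (
    SimulationConfig,
    simulate_cross,
    write_alignments,
    write_fluorescence_tables,
    write_variant_calls,
)


@pytest.fixture(scope="session")
def layout() -> GenomeLayout:
    return GenomeLayout.default()


@pytest.fixture(scope="session")
def grid(layout) -> BinGrid:
    return BinGrid(layout)


@pytest.fixture(scope="session")
def base_config() -> SimulationConfig:
    # decoys and planted filter failures on, so every filter has work to do
    return SimulationConfig(seed=11, decoy_fraction=0.05, filter_fail_fraction=0.05)


@pytest.fixture(scope="session")
def cross(layout, base_config):
    """(mutant_parent, wildtype_parent, offspring list) for the session mix."""
    return simulate_cross(
        layout,
        base_config,
        {"self": 1, "f1": 5, "aneuploid_mono7": 1, "eliminated_tetraploid": 1},
    )


@pytest.fixture(scope="session")
def offspring_by_class(cross):
    _, _, offspring = cross
    by_class: dict[str, list] = {}
    for o in offspring:
        by_class.setdefault(o.class_label, []).append(o)
    return by_class


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, layout, base_config, cross) -> Path:
    """SAM + VCF per offspring, PACE and flow CSVs, written once."""
    mut, wt, offspring = cross
    out = tmp_path_factory.mktemp("simulated_cross")
    for o in offspring:
        write_alignments(o, layout, base_config, out / f"{o.offspring_id}.sam")
        write_variant_calls(o, mut, wt, layout, base_config, out / f"{o.offspring_id}.vcf")
    write_fluorescence_tables(offspring, base_config, out / "pace.csv", out / "flow.csv")
    return out


@pytest.fixture(scope="session")
def control_sams(sim_dir, offspring_by_class):
    """Four diploid (F1) control SAM paths for normalization."""
    return [sim_dir / f"{o.offspring_id}.sam" for o in offspring_by_class["f1"][:4]]


@pytest.fixture(scope="session")
def control_vcfs(sim_dir, offspring_by_class):
    return [sim_dir / f"{o.offspring_id}.vcf" for o in offspring_by_class["f1"][:4]]


# ---------------------------------------------------------------------------
# Brute-force oracles, deliberately independent of the package internals:
# plain text splitting, explicit per-record loops.


def oracle_sam_records(path) -> list[dict]:
    records = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("@"):
            continue
        f = line.split("\t")
        records.append(
            {
                "flag": int(f[1]),
                "chrom": f[2],
                "pos": int(f[3]),
                "mapq": int(f[4]),
                "rnext": f[6],
                "read_len": int(f[5][:-1]) if f[5].endswith("M") else 0,
            }
        )
    return records


def oracle_sam_retained(path) -> list[dict]:
    kept = []
    for r in oracle_sam_records(path):
        if r["flag"] in (83, 99, 147, 163) and r["rnext"] == "=" and r["mapq"] == 60:
            kept.append(r)
    return kept


def oracle_sam_bin_counts(path, bin_size: int, chromosomes) -> dict[str, list[int]]:
    counts = {c: [0] * 20 for c in chromosomes}
    for r in oracle_sam_retained(path):
        mid = (r["pos"] - 1) + r["read_len"] // 2
        b = mid // bin_size
        while b >= len(counts[r["chrom"]]):
            counts[r["chrom"]].append(0)
        counts[r["chrom"]][b] += 1
    return counts


def oracle_vcf_records(path) -> list[dict]:
    records = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            continue
        f = line.split("\t")
        info = dict(kv.split("=") for kv in f[7].split(";"))
        records.append(
            {
                "chrom": f[0],
                "pos": int(f[1]),
                "qual": float(f[5]),
                "dp": int(info["DP"]),
                "scbz": float(info["SCBZ"]),
                "gt": f[9],
            }
        )
    return records


def oracle_vcf_retained_het(path) -> list[dict]:
    kept = []
    for r in oracle_vcf_records(path):
        if r["qual"] <= 140 or r["dp"] > 50 or r["scbz"] > 0:
            continue
        a, b = r["gt"].replace("|", "/").split("/")
        if a != b:
            kept.append(r)
    return kept
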