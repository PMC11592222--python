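import numpy as np
import pytest

import melprs as m


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort with a clear score effect, shared read-only."""
    cfg = m.SimConfig(n_snps=25, n_cases=150, n_controls=160, per_sd_or=2.0, seed=11)
    return m.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def scored_cohort(small_cohort):
    """(cohort, ScoreSet, control mask) for the shared cohort."""
    raw = m.compute_prs(small_cohort.genotypes, small_cohort.weights)
    ctrl = small_cohort.phenotypes["status"].to_numpy() == "control"
    scores = m.standardize(raw, ctrl, small_cohort.genotypes.individual_ids)
    return small_cohort, scores, ctrl


def write_vcf(path, rows, samples, fmt="GT:DP"):
    """Write a minimal VCF v4.2; rows are (chrom, pos, id, ref, alt, calls)."""
    chroms = []
    for r in rows:
        if r[0] not in chroms:
            chroms.append(r[0])
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        *[f"##contig=<ID={c}>" for c in chroms],
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, vid, ref, alt, calls in rows:
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t" + "\t".join(calls)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def weights_from_rows(rows):
    """Rows of (snp_id, chrom, pos, effect, other, beta) -> WeightsTable."""
    return m.WeightsTable([m.SNPWeight(*r) for r in rows])
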