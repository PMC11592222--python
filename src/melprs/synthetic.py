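"""Seeded synthetic case-control cohorts with PRS-linked structure.

Generates the three inputs the pipeline consumes — a SNP weights panel,
genotypes in VCF, and a phenotype table — with the statistical structure
a melanoma PRS case-control study assumes:

* genotypes in Hardy-Weinberg equilibrium at configurable allele
  frequencies (independent SNPs; an optional block-copy mode induces LD
  solely to exercise pruning);
* a retrospective (case-control) design: disease status follows a logistic
  model that is linear in the standardized true score plus age and sex
  effects, and sampling continues until the case and control quotas fill;
* a melanoma-count gradient among cases: the log-odds of each additional
  primary tumor rise with the score (counts capped at 4 = "4 or more");
* score-linked categorical phenotypes (eye/hair color, phototype,
  sunburn frequency, nevus-count category) for cases, with per-variable
  missingness, mirroring a clinic questionnaire available for cases only.

Default sizes and rates emulate a single-center cohort of 270 cases and
296 blood-donor controls: cases older (mean ~57 vs ~41) and less often
male (~43% vs ~72% — the donor series, not melanoma biology, drives the
sex gap), ~65% of cases with multiple primaries, and a ~57-SNP panel
whose raw-score scale (control mean ~1.5, SD ~0.6) matches a GWAS-derived
melanoma panel.

All randomness derives from a single integer seed split into fixed, named
substreams (panel, frequencies, genotypes, status, phenotypes, vcf), so
adding a phenotype draw does not perturb genotype draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix, SNPWeight, WeightsTable, write_weights

__all__ = ["SimConfig", "SyntheticCohort", "sample_weights_panel",
           "simulate_genotypes", "simulate_cohort", "write_cohort"]

# Fixed substream labels: the second word of the Generator seed.
_STREAMS = {"panel": 1, "freqs": 2, "genotypes": 3, "status": 4,
            "phenotypes": 5, "vcf": 6}

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                         ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Generating parameters of a synthetic cohort.

    ``per_sd_or`` is the odds ratio for case status per 1 SD of the true
    score; ``covariate_effects`` holds the age (per year) and male-sex log
    ORs entering the same logit; ``mpm_gradient`` is the log-odds increase
    per score SD of each additional primary melanoma; ``phenotype_assoc``
    maps phenotype categories to log ORs per score SD.
    """

    n_snps: int = 57
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_mean: float = 0.047
    beta_sd: float = 0.13
    ambiguous_fraction: float = 0.0
    n_cases: int = 270
    n_controls: int = 296
    per_sd_or: float = 1.5
    covariate_effects: dict = field(
        default_factory=lambda: {"age_per_year": 0.08, "male": -1.26}
    )
    age_mean: float = 48.5
    age_sd: float = 14.0
    p_male: float = 0.65
    mpm_gradient: float = math.log(1.41)
    mpm_base_logodds: float = 0.62
    phenotype_assoc: dict = field(
        default_factory=lambda: {
            "eye_light": 0.45,
            "hair_blonde": 0.37,
            "hair_red": 0.85,
            "phototype_I_II": 0.55,
            "sunburns_often": 0.48,
            "nevi_gt50": 0.26,
            "family_history": 0.0,
        }
    )
    phenotype_base_rates: dict = field(
        default_factory=lambda: {
            "eye_light": 0.53,
            "hair_blonde": 0.373,
            "hair_red": 0.089,
            "phototype_I_II": 0.53,
            "sunburns_often": 0.558,
            "nevi_gt50": 0.463,
            "family_history": 0.604,
        }
    )
    missing_rates: dict = field(
        default_factory=lambda: {
            "eye_color": 0.126,
            "hair_color": 0.126,
            "phototype": 0.126,
            "sunburns": 0.137,
            "nevi": 0.207,
        }
    )
    age_dx_mean: float = 49.6
    age_dx_sd: float = 14.9
    age_dx_shift_per_sd: float = 4.8
    ld_block_size: int = 1  # >1 enables the block-copy LD mode
    ld_copy_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.beta_sd < 0 or self.per_sd_or <= 0 or self.mpm_gradient < 0:
            raise ValueError("beta_sd, per_sd_or, mpm_gradient out of range")
        if self.n_cases + self.n_controls < 20:
            raise ValueError("need at least 20 individuals in total")


@dataclass
class SyntheticCohort:
    weights: WeightsTable
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict


def sample_weights_panel(
    config: SimConfig, rng: np.random.Generator | None = None
) -> WeightsTable:
    """Random biallelic panel; betas ~ Normal(beta_mean, beta_sd).

    A configurable fraction of SNPs receives a strand-palindromic allele
    pair so the ambiguous-SNP filter can be exercised.
    """
    if rng is None:
        rng = _rng(config.seed, "panel")
    records = []
    for i in range(config.n_snps):
        ambiguous = rng.random() < config.ambiguous_fraction
        pool = _PALINDROMIC_PAIRS if ambiguous else _NONPALINDROMIC_PAIRS
        effect, other = pool[rng.integers(len(pool))]
        beta = config.beta_mean + config.beta_sd * rng.standard_normal()
        records.append(
            SNPWeight(
                snp_id=f"rs{i + 1}",
                chromosome=str(i % 22 + 1),
                position=10_000 * (i + 1),
                effect_allele=effect,
                other_allele=other,
                beta=float(beta),
            )
        )
    return WeightsTable(records)


def simulate_genotypes(
    freqs: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
    snp_ids: list[str] | None = None,
    id_prefix: str = "IND",
) -> GenotypeMatrix:
    """HWE genotypes: dosage_ij ~ Binomial(2, freq_j), independent SNPs."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dosages = rng.binomial(2, freqs, size=(n, freqs.size)).astype(float)
    if snp_ids is None:
        snp_ids = [f"S{j + 1}" for j in range(freqs.size)]
    ids = [f"{id_prefix}{i + 1}" for i in range(n)]
    return GenotypeMatrix(ids, list(snp_ids), dosages)


def _apply_ld_blocks(dosages: np.ndarray, config: SimConfig, rng) -> np.ndarray:
    """Block-copy LD: within a block, each dosage copies the block's first
    SNP with probability ld_copy_prob, else keeps its independent draw."""
    if config.ld_block_size <= 1:
        return dosages
    out = dosages.copy()
    n, m = dosages.shape
    for start in range(0, m, config.ld_block_size):
        for j in range(start + 1, min(start + config.ld_block_size, m)):
            copy = rng.random(n) < config.ld_copy_prob
            out[copy, j] = out[copy, start]
    return out


def _draw_hair(rng, z, config) -> np.ndarray:
    """Three-level hair color from a multinomial logit linked to the score."""
    base = config.phenotype_base_rates
    p_brown = 1.0 - base["hair_blonde"] - base["hair_red"]
    u_blonde = math.log(base["hair_blonde"] / p_brown) + config.phenotype_assoc["hair_blonde"] * z
    u_red = math.log(base["hair_red"] / p_brown) + config.phenotype_assoc["hair_red"] * z
    expu = np.stack([np.ones_like(z), np.exp(u_blonde), np.exp(u_red)])
    probs = (expu / expu.sum(axis=0)).T
    draws = rng.random(z.size)
    cum = np.cumsum(probs, axis=1)
    idx = (draws[:, None] > cum).sum(axis=1)
    return np.array(["brown/black", "blonde", "red"], dtype=object)[idx]


def _draw_binary(rng, z, base_rate, assoc) -> np.ndarray:
    p = _sigmoid(math.log(base_rate / (1 - base_rate)) + assoc * z)
    return rng.random(z.size) < p


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Simulate a full case-control cohort under the configured model.

    Genotypes are drawn under HWE; the true raw score is the weighted
    allele-dosage sum; case status follows
    ``logit(p) = alpha + ln(per_sd_or) * z + b_age*(age - mean) + b_male*male``
    with z the score in population-SD units, the intercept alpha tuned by
    bisection so the expected case fraction matches the requested quota
    ratio; candidates are then sampled until exactly n_cases and
    n_controls are collected. Cases receive melanoma counts, score-linked
    categorical phenotypes and an age at diagnosis; controls carry only
    age, sex and status.
    """
    weights = sample_weights_panel(config)
    freq_rng = _rng(config.seed, "freqs")
    freqs = freq_rng.uniform(*config.maf_range, size=config.n_snps)
    betas = weights.betas

    # Population moments of the raw score under HWE and independence.
    mu = float(np.sum(betas * 2 * freqs))
    var = float(np.sum(betas**2 * 2 * freqs * (1 - freqs)))
    if var == 0.0:
        raise ValueError("degenerate score: zero variance (all betas or freqs trivial)")
    sd = math.sqrt(var)

    b_score = math.log(config.per_sd_or)
    b_age = float(config.covariate_effects.get("age_per_year", 0.0))
    b_male = float(config.covariate_effects.get("male", 0.0))
    target = config.n_cases / (config.n_cases + config.n_controls)

    geno_rng = _rng(config.seed, "genotypes")
    status_rng = _rng(config.seed, "status")

    def draw_candidates(n: int):
        dos = geno_rng.binomial(2, freqs, size=(n, config.n_snps)).astype(float)
        dos = _apply_ld_blocks(dos, config, geno_rng)
        z = (dos @ betas - mu) / sd
        age = config.age_mean + config.age_sd * status_rng.standard_normal(n)
        male = (status_rng.random(n) < config.p_male).astype(float)
        return dos, z, age, male

    # Calibrate the intercept on a dedicated candidate pool.
    cal_n = 8_000
    _, z_cal, age_cal, male_cal = draw_candidates(cal_n)
    lin = b_score * z_cal + b_age * (age_cal - config.age_mean) + b_male * male_cal

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if _sigmoid(mid + lin).mean() < target:
            lo = mid
        else:
            hi = mid
    alpha = (lo + hi) / 2

    # Retrospective sampling until both quotas fill.
    need_case, need_ctrl = config.n_cases, config.n_controls
    rows_dos, rows_z, rows_age, rows_male, rows_status = [], [], [], [], []
    max_draws = 200 * (config.n_cases + config.n_controls) + 100_000
    drawn = 0
    batch = max(2 * (config.n_cases + config.n_controls), 1000)
    while need_case > 0 or need_ctrl > 0:
        if drawn > max_draws:
            raise RuntimeError(
                "case/control quotas unattainable under the configured effects"
            )
        dos, z, age, male = draw_candidates(batch)
        drawn += batch
        p = _sigmoid(alpha + b_score * z + b_age * (age - config.age_mean) + b_male * male)
        is_case = status_rng.random(batch) < p
        for i in range(batch):
            if is_case[i] and need_case > 0:
                take, status = True, 1
                need_case -= 1
            elif not is_case[i] and need_ctrl > 0:
                take, status = True, 0
                need_ctrl -= 1
            else:
                take = False
            if take:
                rows_dos.append(dos[i])
                rows_z.append(z[i])
                rows_age.append(age[i])
                rows_male.append(male[i])
                rows_status.append(status)
            if need_case == 0 and need_ctrl == 0:
                break

    dosages = np.asarray(rows_dos)
    z = np.asarray(rows_z)
    age = np.asarray(rows_age)
    male = np.asarray(rows_male)
    status = np.asarray(rows_status)
    n_total = status.size
    ids = [f"IND{i + 1}" for i in range(n_total)]
    genotypes = GenotypeMatrix(ids, weights.snp_ids, dosages)

    # Phenotypes: clinic questionnaire exists for cases only.
    pheno_rng = _rng(config.seed, "phenotypes")
    case = status == 1
    zc = z[case]
    n_case = int(case.sum())

    n_mel = np.zeros(n_total)
    n_mel[case] = 1
    p_more = _sigmoid(config.mpm_base_logodds + config.mpm_gradient * zc)
    counts = np.ones(n_case)
    active = np.ones(n_case, dtype=bool)
    for _ in range(3):  # sequential growth, capped at 4 ("4 or more")
        grow = active & (pheno_rng.random(n_case) < p_more)
        counts += grow
        active = grow  # failing one step ends the sequence
    n_mel[case] = counts

    base = config.phenotype_base_rates
    assoc = config.phenotype_assoc
    eye = np.where(_draw_binary(pheno_rng, zc, base["eye_light"], assoc["eye_light"]),
                   "light", "dark")
    hair = _draw_hair(pheno_rng, zc, config)
    photo = np.where(
        _draw_binary(pheno_rng, zc, base["phototype_I_II"], assoc["phototype_I_II"]),
        "I-II", "III-IV")
    sunb = np.where(
        _draw_binary(pheno_rng, zc, base["sunburns_often"], assoc["sunburns_often"]),
        "often", "rarely/never")
    nevi = np.where(_draw_binary(pheno_rng, zc, base["nevi_gt50"], assoc["nevi_gt50"]),
                    ">50", "<50")
    famhx = np.where(
        _draw_binary(pheno_rng, zc, base["family_history"], assoc["family_history"]),
        "yes", "no")
    age_dx = (config.age_dx_mean - config.age_dx_shift_per_sd * zc
              + config.age_dx_sd * pheno_rng.standard_normal(n_case))

    def case_col(values, fill=np.nan):
        col = np.full(n_total, fill, dtype=object)
        col[case] = values
        return col

    pheno = pd.DataFrame(
        {
            "individual_id": ids,
            "status": np.where(case, "case", "control"),
            "age_at_sampling": np.round(age, 1),
            "age_at_diagnosis": case_col(np.round(age_dx, 1)),
            "sex": np.where(male == 1, "M", "F"),
            "eye_color": case_col(eye),
            "hair_color": case_col(hair),
            "phototype": case_col(photo),
            "sunburns": case_col(sunb),
            "nevi": case_col(nevi),
            "family_history": case_col(famhx),
            "n_melanomas": n_mel.astype(int),
        }
    )
    # Per-variable missingness among cases, as in a clinic questionnaire.
    for col, rate in config.missing_rates.items():
        if rate <= 0:
            continue
        hit = case & (pheno_rng.random(n_total) < rate)
        pheno.loc[hit, col] = np.nan

    truth = {
        "seed": config.seed,
        "freqs": freqs.tolist(),
        "betas": betas.tolist(),
        "raw_score_mean": mu,
        "raw_score_sd": sd,
        "alpha": alpha,
        "per_sd_or": config.per_sd_or,
        "covariate_effects": dict(config.covariate_effects),
        "mpm_gradient": config.mpm_gradient,
        "phenotype_assoc": dict(config.phenotype_assoc),
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
    }
    return SyntheticCohort(weights=weights, genotypes=genotypes,
                           phenotypes=pheno, truth=truth)


def write_cohort(
    cohort: SyntheticCohort,
    directory: str | Path,
    dp: int = 100,
    low_depth_rate: float = 0.0,
    low_depth_value: int = 12,
) -> dict[str, Path]:
    """Write weights TSV, VCF (v4.2, GT:DP), phenotype TSV and truth JSON.

    VCF REF/ALT orientation is randomized per site (seeded from the
    cohort's own seed), so reading the files back exercises allele
    flipping. ``low_depth_rate`` injects per-genotype DP values of
    ``low_depth_value`` to exercise the read-depth filter. Output is
    byte-identical for the same cohort and arguments.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": directory / "weights.tsv",
        "vcf": directory / "genotypes.vcf",
        "phenotypes": directory / "phenotypes.tsv",
        "truth": directory / "truth.json",
    }
    write_weights(cohort.weights, paths["weights"])
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False, na_rep="NA")
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2) + "\n")

    rng = _rng(int(cohort.truth.get("seed", 0)), "vcf")
    def chrom_key(r):
        try:
            return (0, int(r.chromosome), r.position)
        except ValueError:
            return (1, 0, r.position)

    recs = sorted(cohort.weights.records, key=chrom_key)
    col = {s: j for j, s in enumerate(cohort.genotypes.snp_ids)}
    samples = cohort.genotypes.individual_ids

    contigs = []
    for rec in recs:
        if rec.chromosome not in contigs:
            contigs.append(rec.chromosome)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        *[f"##contig=<ID={c}>" for c in contigs],
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    for rec in recs:
        effect_is_alt = bool(rng.random() < 0.5)
        ref, alt = ((rec.other_allele, rec.effect_allele) if effect_is_alt
                    else (rec.effect_allele, rec.other_allele))
        doses = cohort.genotypes.dosages[:, col[rec.snp_id]]
        low = rng.random(len(samples)) < low_depth_rate if low_depth_rate > 0 else None
        fields = []
        for i, d in enumerate(doses):
            if np.isnan(d):
                gt = "./."
            else:
                alt_count = int(d) if effect_is_alt else 2 - int(d)
                gt = gt_strings[alt_count]
            depth = low_depth_value if (low is not None and low[i]) else dp
            fields.append(f"{gt}:{depth}")
        lines.append(
            f"{rec.chromosome}\t{rec.position}\t{rec.snp_id}\t{ref}\t{alt}"
            f"\t.\tPASS\t.\tGT:DP\t" + "\t".join(fields)
        )
    paths["vcf"].write_text("\n".join(lines) + "\n")
    return paths
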