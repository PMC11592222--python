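"""Weights/genotype input and SNP-level quality control.

Reads a per-SNP weights table (effect allele + per-allele log odds ratio)
and sample genotypes from VCF, resolves allele orientation so dosages count
effect alleles, and applies the panel-level filters used when assembling a
PRS SNP panel: removal of strand-ambiguous (palindromic) SNPs and greedy
LD pruning on pairwise genotype r².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SNPWeight",
    "WeightsTable",
    "GenotypeMatrix",
    "QCReport",
    "read_weights",
    "write_weights",
    "read_genotypes_vcf",
    "filter_ambiguous",
    "genotype_r2",
    "ld_prune",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Allele pairs indistinguishable between strands.
_PALINDROMIC = (frozenset("AT"), frozenset("CG"))

WEIGHTS_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta"]


class AlleleMismatchError(ValueError):
    """VCF REF/ALT alleles are incompatible with the weight record."""


@dataclass(frozen=True)
class SNPWeight:
    """One panel SNP: identity, alleles, and its per-allele log OR."""

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in _VALID_ALLELES:
                raise ValueError(f"{self.snp_id}: allele {allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: beta must be finite")

    @property
    def allele_pair(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def is_ambiguous(self) -> bool:
        """True for strand-palindromic pairs {A,T} or {C,G}."""
        return self.allele_pair in _PALINDROMIC


@dataclass
class WeightsTable:
    """Ordered SNP weight panel with unique ids and positions."""

    records: list[SNPWeight]

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_id(s): {', '.join(dupes)}")
        locs = [(r.chromosome, r.position) for r in self.records]
        if len(set(locs)) != len(locs):
            raise ValueError("duplicate (chromosome, position) in weights table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    @property
    def betas(self) -> np.ndarray:
        return np.array([r.beta for r in self.records], dtype=float)

    def subset(self, snp_ids: Sequence[str]) -> "WeightsTable":
        keep = set(snp_ids)
        return WeightsTable([r for r in self.records if r.snp_id in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.snp_id, r.chromosome, r.position, r.effect_allele, r.other_allele, r.beta)
                for r in self.records
            ],
            columns=WEIGHTS_COLUMNS,
        )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs effect-allele dosages; NaN encodes missing."""

    individual_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float array, values in {0, 1, 2, nan}

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match id lists")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            list(self.individual_ids), list(snp_ids), self.dosages[:, idx].copy()
        )


@dataclass
class QCReport:
    """Record of panel removals and genotype-level masking."""

    removed_ambiguous: list[str] = field(default_factory=list)
    removed_ld: list[tuple[str, str, float]] = field(default_factory=list)
    genotypes_set_missing_low_depth: int = 0
    sites_absent_from_vcf: list[str] = field(default_factory=list)

    def merged_with(self, other: "QCReport") -> "QCReport":
        return QCReport(
            self.removed_ambiguous + other.removed_ambiguous,
            self.removed_ld + other.removed_ld,
            self.genotypes_set_missing_low_depth + other.genotypes_set_missing_low_depth,
            self.sites_absent_from_vcf + other.sites_absent_from_vcf,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_weights(path: str | Path) -> WeightsTable:
    """Read a tab- or comma-delimited weights table.

    The header must name snp_id, chrom, pos, effect_allele, other_allele
    and beta (order free). Row order is preserved.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = set(WEIGHTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weights file missing column(s): {', '.join(sorted(missing))}")
    records = []
    for row in df.itertuples(index=False):
        try:
            beta = float(getattr(row, "beta"))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unparseable beta for {row.snp_id!r}: {row.beta!r}") from exc
        records.append(
            SNPWeight(
                snp_id=str(row.snp_id),
                chromosome=str(row.chrom),
                position=int(row.pos),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                beta=beta,
            )
        )
    return WeightsTable(records)


def write_weights(weights: WeightsTable, path: str | Path) -> Path:
    path = Path(path)
    weights.to_frame().to_csv(path, sep="\t", index=False)
    return path


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def read_genotypes_vcf(
    path: str | Path,
    weights: WeightsTable,
    min_depth: int = 30,
    normalize_chr_prefix: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Read effect-allele dosages for the panel SNPs from a VCF.

    Sites are matched to weight records on (chromosome, position); REF/ALT
    must equal the record's allele pair in either orientation. When the
    effect allele is the VCF REF the dosage is flipped (2 - ALT count).
    A genotype is set missing when GT is missing or its per-sample DP is
    below ``min_depth`` (DP absent => no depth filter). Panel SNPs absent
    from the VCF yield an all-missing column, noted in the QC report.

    Strand-complement matches are NOT rescued: a REF/ALT pair equal to the
    complement of the weight alleles raises :class:`AlleleMismatchError`
    (silent strand errors are worse than a hard failure). Multi-allelic
    sites raise.
    """
    from cyvcf2 import VCF

    def key(chrom: str, pos: int) -> tuple[str, int]:
        return (_strip_chr(chrom) if normalize_chr_prefix else chrom, pos)

    by_loc = {key(r.chromosome, r.position): r for r in weights.records}
    col_of = {r.snp_id: j for j, r in enumerate(weights.records)}

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages = np.full((len(samples), len(weights)), np.nan)
    seen: set[str] = set()
    n_low_depth = 0

    for variant in vcf:
        rec = by_loc.get(key(variant.CHROM, variant.POS))
        if rec is None:
            continue
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{rec.snp_id}: multi-allelic site at {variant.CHROM}:{variant.POS}"
            )
        ref, alt = variant.REF.upper(), variant.ALT[0].upper()
        pair = frozenset((ref, alt))
        if pair != rec.allele_pair:
            comp = frozenset(_COMPLEMENT[a] for a in rec.allele_pair if a in _COMPLEMENT)
            if pair == comp:
                raise AlleleMismatchError(
                    f"{rec.snp_id}: VCF alleles {ref}/{alt} are the strand complement "
                    f"of {rec.effect_allele}/{rec.other_allele}; check strand"
                )
            raise AlleleMismatchError(
                f"{rec.snp_id}: VCF alleles {ref}/{alt} incompatible with "
                f"{rec.effect_allele}/{rec.other_allele}"
            )
        seen.add(rec.snp_id)
        j = col_of[rec.snp_id]

        # ALT-allele count per sample; -1 marks an unknown genotype.
        gts = variant.genotype.array()
        alleles = gts[:, :-1]
        unknown = (alleles < 0).any(axis=1)
        alt_count = (alleles > 0).sum(axis=1).astype(float)
        dose = alt_count if rec.effect_allele == alt else 2.0 - alt_count
        dose[unknown] = np.nan

        depths = variant.format("DP")
        if depths is not None:
            low = (depths[:, 0] < min_depth) & ~unknown
            n_low_depth += int(low.sum())
            dose[low] = np.nan
        dosages[:, j] = dose

    report = QCReport(
        genotypes_set_missing_low_depth=n_low_depth,
        sites_absent_from_vcf=[s for s in weights.snp_ids if s not in seen],
    )
    return GenotypeMatrix(samples, weights.snp_ids, dosages), report


def filter_ambiguous(weights: WeightsTable) -> tuple[WeightsTable, QCReport]:
    """Drop strand-palindromic SNPs ({A,T} or {C,G}); keep the rest in order."""
    kept = [r for r in weights.records if not r.is_ambiguous]
    removed = [r.snp_id for r in weights.records if r.is_ambiguous]
    return WeightsTable(kept), QCReport(removed_ambiguous=removed)


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs.

    Pairs with a missing (NaN) value in either vector are excluded. Raises
    if fewer than two complete pairs remain or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("need at least 2 complete pairs for r2")
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        raise ValueError("r2 undefined: zero variance in a dosage vector")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    r2 = cov * cov / (vx * vy)
    return float(min(r2, 1.0))


def ld_prune(
    matrix: GenotypeMatrix,
    weights: WeightsTable,
    max_r2: float = 0.45,
) -> tuple[list[str], QCReport]:
    """Greedily prune SNP pairs with genotype r² above ``max_r2``.

    SNPs are scanned in (chromosome, position) order; whenever a retained
    pair violates the threshold, the member with the smaller |beta| is
    dropped (ties: the later in scan order). The retained set therefore
    has no pair with r² above the threshold. Pairs where r² is undefined
    (a constant or near-empty column) never force a drop.
    """
    recs = {r.snp_id: r for r in weights.records}
    order = sorted(
        (s for s in matrix.snp_ids if s in recs),
        key=lambda s: (recs[s].chromosome, recs[s].position),
    )
    rank = {s: i for i, s in enumerate(order)}
    cols = {s: matrix.column(s) for s in order}

    retained = list(order)
    dropped: list[tuple[str, str, float]] = []
    changed = True
    while changed:
        changed = False
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                a, b = retained[i], retained[j]
                try:
                    r2 = genotype_r2(cols[a], cols[b])
                except ValueError:
                    continue
                if r2 <= max_r2:
                    continue
                ba, bb = abs(recs[a].beta), abs(recs[b].beta)
                if ba > bb or (ba == bb and rank[a] < rank[b]):
                    keep, drop = a, b
                else:
                    keep, drop = b, a
                retained.remove(drop)
                dropped.append((keep, drop, r2))
                changed = True
                break
            if changed:
                break

    # Restore the original matrix column order among survivors.
    retained_in_input_order = [s for s in matrix.snp_ids if s in set(retained)]
    return retained_in_input_order, QCReport(removed_ld=dropped)
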