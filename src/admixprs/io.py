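"""Readers, writers and harmonization for the pipeline's standard formats.

Summary statistics come in as a delimited table with a configurable
column map; genotypes come in as VCF 4.2 (DS dosage preferred over GT
hard calls; phased haplotypes retained only when every genotype in the
region is phased); the cohort table is a TSV of per-subject phenotype
and covariates. Harmonization aligns the discovery effect alleles to
the target VCF's ref/alt labels, sign-flipping betas where needed.

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
#: Allele pairs that cannot be disambiguated across strand flips.
STRAND_AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))

#: Default header names for summary-statistics tables.
DEFAULT_SUMSTAT_COLUMNS = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "eaf": "eaf",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One discovery-GWAS variant: alleles, log-odds effect, SE, p, frequency."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.variant_id}: pvalue {self.pvalue} outside (0, 1]")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be positive")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta not finite")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.variant_id}: eaf outside [0, 1]")

    @property
    def is_strand_ambiguous(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in STRAND_AMBIGUOUS_PAIRS


@dataclass
class GenotypeSet:
    """Sample × variant effect-allele dosages plus optional phased haplotypes.

    ``variants`` is a DataFrame with columns variant_id, chrom, pos, ref,
    alt (positions strictly increasing within each chromosome).
    ``dosage`` holds alt-allele dosages in [0, 2] (NaN = missing);
    ``phased`` is an optional (n_samples, n_variants, 2) int8 array of
    0/1 alt-allele indicators, one entry per chromosome copy.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    phased: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows must match sample_ids")
        if m != len(self.variants):
            raise ValueError("dosage columns must match variants")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosage entries must lie in [0, 2]")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("variant positions must be strictly increasing per chromosome")
        if self.phased is not None:
            if self.phased.shape != (n, m, 2):
                raise ValueError("phased must have shape (n_samples, n_variants, 2)")
            obs = ~np.isnan(self.dosage)
            hard = obs & (np.round(self.dosage) == self.dosage)
            if not np.array_equal(self.phased.sum(axis=2)[hard], self.dosage[hard]):
                raise ValueError("phased alleles must sum to the hard-call dosage")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def alt_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency from mean dosage / 2."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.alt_freq
        return np.minimum(f, 1.0 - f)

    def variant_index(self) -> dict[str, int]:
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise FormatError(f"duplicate variant ids in genotype set: {dups[:5]}")
        return {vid: i for i, vid in enumerate(ids)}

    def subset_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeSet":
        idx = np.asarray(idx, dtype=int)
        return GenotypeSet(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            phased=None if self.phased is None else self.phased[:, idx, :],
        )

    def subset_samples(self, keep_ids: Sequence[str]) -> "GenotypeSet":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in keep_ids], dtype=int)
        return GenotypeSet(
            sample_ids=list(keep_ids),
            variants=self.variants.copy(),
            dosage=self.dosage[idx, :],
            phased=None if self.phased is None else self.phased[idx, :, :],
        )


@dataclass
class HarmonizedStats:
    """Summary statistics aligned to a genotype set's alt-allele dosages.

    ``flip`` marks variants whose effect allele is the VCF ref: for those
    the effective dosage is 2 − alt dosage, so that every variant is
    scored on its effect-allele count with the discovery beta unchanged.
    This makes scoring exactly invariant to ref/alt relabeling in the
    VCF. ``col`` gives each variant's dosage column.
    """

    variant_ids: list[str]
    col: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    flip: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variant_ids)

    def aligned_dosage(self, genotypes: GenotypeSet) -> np.ndarray:
        """Effect-allele dosage matrix (n_samples × n_kept variants)."""
        d = genotypes.dosage[:, self.col].astype(float, copy=True)
        d[:, self.flip] = 2.0 - d[:, self.flip]
        return d

    def subset(self, mask: np.ndarray) -> "HarmonizedStats":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return HarmonizedStats(
            variant_ids=[self.variant_ids[i] for i in idx],
            col=self.col[idx],
            beta=self.beta[idx],
            se=self.se[idx],
            pvalue=self.pvalue[idx],
            flip=self.flip[idx],
            dropped=list(self.dropped),
        )


def read_summary_stats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> tuple[list[SummaryStatRecord], int]:
    """Parse a delimited summary-statistics table.

    Returns the parsed records and the number of rejected rows; each
    rejection is logged with its reason. A missing required column is a
    :class:`FormatError` (``eaf`` is optional).
    """
    cmap = dict(DEFAULT_SUMSTAT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = [k for k in cmap if k != "eaf"]
    missing = [cmap[k] for k in required if cmap[k] not in df.columns]
    if missing:
        raise FormatError(f"summary statistics missing required column(s): {missing}")
    has_eaf = cmap["eaf"] in df.columns

    records: list[SummaryStatRecord] = []
    n_rejected = 0
    for i, row in df.iterrows():
        try:
            eaf = None
            if has_eaf and pd.notna(row[cmap["eaf"]]) and str(row[cmap["eaf"]]) != "":
                eaf = float(row[cmap["eaf"]])
            rec = SummaryStatRecord(
                variant_id=str(row[cmap["variant_id"]]),
                chrom=str(row[cmap["chrom"]]),
                pos=int(row[cmap["pos"]]),
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pvalue=float(row[cmap["pvalue"]]),
                eaf=eaf,
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("summary-stats row %d rejected: %s", i, exc)
            continue
        records.append(rec)
    logger.info("parsed %d summary-stat records (%d rejected)", len(records), n_rejected)
    return records, n_rejected


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": repr(float(r.beta)),
                "se": repr(float(r.se)),
                "pvalue": repr(float(r.pvalue)),
                "eaf": "" if r.eaf is None else repr(float(r.eaf)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def remove_strand_ambiguous(
    records: Iterable[SummaryStatRecord],
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord]]:
    """Partition records into (kept, removed) by CG/AT strand ambiguity."""
    kept: list[SummaryStatRecord] = []
    removed: list[SummaryStatRecord] = []
    for rec in records:
        (removed if rec.is_strand_ambiguous else kept).append(rec)
    if removed:
        logger.info("removed %d strand-ambiguous variants", len(removed))
    return kept, removed


def harmonize(
    records: Sequence[SummaryStatRecord], genotypes: GenotypeSet
) -> HarmonizedStats:
    """Align discovery effect alleles to the target VCF's ref/alt labels.

    effect == alt uses the alt dosage directly; effect == ref marks the
    variant flipped so the aligned dosage becomes 2 − alt dosage (the
    effect-allele count); any other allele configuration drops the
    variant with a log entry. Duplicate variant ids in either input
    raise :class:`FormatError`.
    """
    seen: set[str] = set()
    for rec in records:
        if rec.variant_id in seen:
            raise FormatError(f"duplicate variant id in summary stats: {rec.variant_id}")
        seen.add(rec.variant_id)
    vindex = genotypes.variant_index()  # raises on duplicate ids
    ref = genotypes.variants["ref"].to_numpy()
    alt = genotypes.variants["alt"].to_numpy()

    ids: list[str] = []
    cols: list[int] = []
    betas: list[float] = []
    ses: list[float] = []
    ps: list[float] = []
    flips: list[bool] = []
    dropped: list[str] = []
    for rec in records:
        j = vindex.get(rec.variant_id)
        if j is None:
            dropped.append(rec.variant_id)
            continue
        if rec.effect_allele == alt[j] and rec.other_allele == ref[j]:
            flip = False
        elif rec.effect_allele == ref[j] and rec.other_allele == alt[j]:
            flip = True
        else:
            dropped.append(rec.variant_id)
            logger.info(
                "variant %s dropped: alleles %s/%s do not match VCF %s/%s",
                rec.variant_id, rec.effect_allele, rec.other_allele, ref[j], alt[j],
            )
            continue
        ids.append(rec.variant_id)
        cols.append(j)
        betas.append(rec.beta)
        ses.append(rec.se)
        ps.append(rec.pvalue)
        flips.append(flip)
    return HarmonizedStats(
        variant_ids=ids,
        col=np.asarray(cols, dtype=int),
        beta=np.asarray(betas, dtype=float),
        se=np.asarray(ses, dtype=float),
        pvalue=np.asarray(ps, dtype=float),
        flip=np.asarray(flips, dtype=bool),
        dropped=dropped,
    )


def read_vcf(path: str | Path, region: str | None = None) -> GenotypeSet:
    """Load a VCF into a :class:`GenotypeSet`.

    DS (dosage) is used when present, otherwise GT hard calls. Phased
    haplotypes are populated only when every genotype in the region uses
    the phased separator. Multi-allelic sites are skipped with a log
    entry.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    n = len(sample_ids)

    rows = []
    dosage_cols: list[np.ndarray] = []
    phased_cols: list[np.ndarray] = []
    all_phased = True
    iterator = vcf(region) if region else vcf
    for var in iterator:
        if len(var.ALT) != 1:
            logger.info("skipping multi-allelic site %s:%d", var.CHROM, var.POS)
            continue
        gts = np.array(var.genotypes, dtype=object)  # rows: [a0, a1, phased]
        a0 = np.array([g[0] for g in gts], dtype=float)
        a1 = np.array([g[1] for g in gts], dtype=float)
        phased_flags = np.array([bool(g[2]) for g in gts])
        a0[a0 < 0] = np.nan
        a1[a1 < 0] = np.nan
        hard = a0 + a1

        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = ds.astype(float).reshape(n)
            d[d < 0] = np.nan  # negative sentinel = missing
        else:
            d = hard
        if not phased_flags.all() or np.isnan(a0).any():
            all_phased = False
        rows.append(
            {
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
        dosage_cols.append(d)
        phased_cols.append(np.stack([a0, a1], axis=1))
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    dosage = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((n, 0))
    )
    phased = None
    if all_phased and phased_cols:
        phased = np.stack(phased_cols, axis=1).astype(np.int8)
    return GenotypeSet(sample_ids=sample_ids, variants=variants, dosage=dosage, phased=phased)


def write_vcf(genotypes: GenotypeSet, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT (phased when available) and DS.

    Output is byte-deterministic: no timestamps, fixed field order.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        phased = genotypes.phased
        for j, var in genotypes.variants.iterrows():
            fields = [
                str(var["chrom"]), str(var["pos"]),
                str(var["variant_id"]), str(var["ref"]), str(var["alt"]),
                ".", "PASS", ".", "GT:DS",
            ]
            for i in range(genotypes.n_samples):
                d = genotypes.dosage[i, j]
                if phased is not None:
                    gt = f"{phased[i, j, 0]}|{phased[i, j, 1]}"
                elif np.isnan(d):
                    gt = "./."
                else:
                    h = int(round(d))
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(h, 0), 2)]
                ds = "." if np.isnan(d) else f"{d:g}"
                fields.append(f"{gt}:{ds}")
            fh.write("\t".join(fields) + "\n")


COHORT_REQUIRED = ("sample_id", "status", "sex", "age")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the per-subject phenotype/covariate table invariants."""
    missing = [c for c in COHORT_REQUIRED if c not in cohort.columns]
    if missing:
        raise FormatError(f"cohort table missing column(s): {missing}")
    status = cohort["status"]
    if not set(status.dropna().unique()) <= {0, 1}:
        raise FormatError("status must be binary 0/1")
    if "age_at_onset" in cohort.columns:
        has_onset = cohort["age_at_onset"].notna()
        if (cohort.loc[has_onset, "status"] != 1).any():
            raise FormatError("age_at_onset present for a control")
        bad = has_onset & (cohort["age_at_onset"] > cohort["age"])
        if bad.any():
            raise FormatError("age_at_onset exceeds age at analysis")
    return cohort


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = df["sample_id"].astype(str)
    return validate_cohort(df)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort).to_csv(path, sep="\t", index=False)
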