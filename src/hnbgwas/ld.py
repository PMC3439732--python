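"""Feature screening and LD-block schema construction.

The pre-processing protocol: quality-control SNPs (missingness, MAF,
Hardy-Weinberg exact test in controls), rank SNPs by a 2-df Pearson
chi-square case/control genotype test, keep the top k (500 by default),
then scan the selected SNPs in position order and group runs of adjacent
markers whose pairwise genotype r-squared stays above a threshold into
LD blocks.  SNPs left outside any block become independent covariates.
The resulting :class:`BlockSchema` is learned once on a screening set
and then applied, frozen (including its minor-allele definitions), to
replication data.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CONTROL, MISSING, GenotypeDataset

N_STATES = 3


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    id: str
    chrom: str
    snp_ids: tuple

    def __len__(self):
        return len(self.snp_ids)


@dataclass
class BlockSchema:
    """Partition of the selected SNPs into LD blocks plus covariates.

    ``minor_alleles`` maps every selected SNP (block member or covariate)
    to the allele whose dosage is counted, as defined on the screening
    set; :func:`apply_schema` re-codes any dataset to these definitions.
    Blocks built by :func:`build_ld_blocks` always have >= 2 SNPs
    (singletons are demoted to covariates), but hand-built schemas with
    singleton blocks are accepted, which makes the model reduce exactly
    to plain Naive Bayes.
    """

    blocks: list
    covariates: list
    minor_alleles: dict
    r2_threshold: float
    selection_k: int = 500
    provenance: str = ""

    @property
    def snp_ids(self) -> list:
        out = []
        for b in self.blocks:
            out.extend(b.snp_ids)
        out.extend(self.covariates)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "blocks": [
                    {"id": b.id, "chrom": b.chrom, "snp_ids": list(b.snp_ids)}
                    for b in self.blocks
                ],
                "covariates": list(self.covariates),
                "minor_alleles": dict(self.minor_alleles),
                "r2_threshold": self.r2_threshold,
                "selection_k": self.selection_k,
                "provenance": self.provenance,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BlockSchema":
        d = json.loads(text)
        return cls(
            blocks=[
                Block(b["id"], b["chrom"], tuple(b["snp_ids"])) for b in d["blocks"]
            ],
            covariates=d["covariates"],
            minor_alleles=d["minor_alleles"],
            r2_threshold=d["r2_threshold"],
            selection_k=d["selection_k"],
            provenance=d.get("provenance", ""),
        )


# ---------------------------------------------------------------------------
# SNP-level QC
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums, over the conditional distribution of the heterozygote count
    given the allele counts, the probabilities of all configurations no
    more probable than the observed one (two-sided exact test, computed
    with the standard stable recurrence).
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote count has the parity of the rare-allele count
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    het_probs = {}
    het_probs[mid] = 1.0
    # downward recurrence P(h-2)/P(h) = h(h-1) / (4 (hr+1)(hc+1))
    h, hr, hc = mid, (n_rare - mid) // 2, (2 * n - n_rare - mid) // 2
    while h >= 2:
        het_probs[h - 2] = het_probs[h] * h * (h - 1) / (4.0 * (hr + 1) * (hc + 1))
        h, hr, hc = h - 2, hr + 1, hc + 1
    # upward recurrence P(h+2)/P(h) = 4 hr hc / ((h+2)(h+1))
    h, hr, hc = mid, (n_rare - mid) // 2, (2 * n - n_rare - mid) // 2
    while h + 2 <= min(n_rare, 2 * n - n_rare):
        het_probs[h + 2] = het_probs[h] * 4.0 * hr * hc / ((h + 2) * (h + 1))
        h, hr, hc = h + 2, hr - 1, hc - 1
    total = sum(het_probs.values())
    obs = het_probs[n_het] / total
    p = sum(v for v in het_probs.values() if v / total <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def snp_qc(
    dataset: GenotypeDataset,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
    hwe_p_min: float = 5.7e-7,
):
    """Drop SNPs failing missingness, MAF or control-HWE filters.

    Returns (filtered dataset, per-SNP report DataFrame).  HWE is tested
    in controls only; if no controls are present the HWE filter is
    skipped with a warning.
    """
    miss = dataset.missingness()
    maf = dataset.minor_allele_frequency()
    maf = np.minimum(maf, 1 - maf)  # guard: counted allele may drift major
    controls = dataset.labels == CONTROL
    if controls.any():
        counts = dataset.genotype_counts(mask=controls)
        hwe_p = np.array(
            [hwe_exact_p(int(c[1]), int(c[0]), int(c[2])) for c in counts]
        )
    else:
        warnings.warn("no controls present; HWE filter skipped")
        hwe_p = np.ones(dataset.n_snps)

    reasons = np.array([""] * dataset.n_snps, dtype=object)
    fail_miss = miss > max_missing
    fail_maf = maf < min_maf
    fail_hwe = hwe_p < hwe_p_min
    reasons[fail_hwe] = "hwe"
    reasons[fail_maf] = "maf"
    reasons[fail_miss] = "missingness"  # first-listed reason wins
    keep = ~(fail_miss | fail_maf | fail_hwe)
    report = pd.DataFrame(
        {
            "snp": dataset.snp_ids,
            "missing_frac": miss,
            "maf": maf,
            "hwe_p_controls": hwe_p,
            "pass": keep,
            "reason": reasons,
        }
    )
    kept = [s for s, k in zip(dataset.snp_ids, keep) if k]
    return dataset.subset_snps(kept), report


# ---------------------------------------------------------------------------
# Association screening
# ---------------------------------------------------------------------------

def chi2_2df(table) -> tuple:
    """Pearson chi-square genotype test on a 2x3 case/control table.

    Degrees of freedom = (number of non-degenerate genotype columns - 1);
    columns with zero margin are dropped.  Returns (statistic, p).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2 x S")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row = t.sum(axis=1)
    if (row == 0).any():
        raise ValueError("zero row margin: a class has no observations")
    col = t.sum(axis=0)
    keep = col > 0
    df = int(keep.sum()) - 1
    if df < 1:
        return 0.0, 1.0
    t = t[:, keep]
    e = np.outer(row, t.sum(axis=0)) / t.sum()
    stat = float(((t - e) ** 2 / e).sum())
    return stat, float(stats.chi2.sf(stat, df))


def chi2_scan(dataset: GenotypeDataset) -> pd.DataFrame:
    """Vectorized per-SNP 2-df chi-square scan; returns stat, df, p."""
    labels = dataset.labels
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two phenotype classes")
    obs = np.stack(
        [dataset.genotype_counts(mask=labels == c) for c in classes], axis=1
    ).astype(float)  # (M, 2, 3)
    row = obs.sum(axis=2)  # (M, 2)
    if (row == 0).any():
        raise ValueError("a class has no observed genotypes for some SNP")
    col = obs.sum(axis=1)  # (M, 3)
    tot = row.sum(axis=1)  # (M,)
    e = row[:, :, None] * col[:, None, :] / tot[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(e > 0, (obs - e) ** 2 / e, 0.0)
    stat = cells.sum(axis=(1, 2))
    df = (col > 0).sum(axis=1) - 1
    p = np.where(df >= 1, stats.chi2.sf(stat, np.maximum(df, 1)), 1.0)
    stat = np.where(df >= 1, stat, 0.0)
    return pd.DataFrame(
        {
            "snp": dataset.snp_ids,
            "chrom": dataset.chrom.astype(str),
            "pos": dataset.pos,
            "chi2": stat,
            "df": df,
            "p": p,
        }
    )


def select_top_k(dataset: GenotypeDataset, k: int = 500) -> list:
    """Top-k SNP ids by ascending chi-square p-value.

    Ties resolve by (chromosome, position) so the ranking is
    deterministic; returns min(k, available) ids.
    """
    scan = chi2_scan(dataset)
    ranked = scan.sort_values(["p", "chrom", "pos"], kind="mergesort")
    return ranked["snp"].head(k).tolist()


# ---------------------------------------------------------------------------
# LD blocks
# ---------------------------------------------------------------------------

def genotype_r2(g1, g2) -> float:
    """Squared Pearson correlation of dosages (composite LD), in [0, 1].

    Missing genotypes are handled pairwise-complete; a monomorphic SNP
    (or fewer than two complete pairs) gives 0.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        warnings.warn("fewer than 2 complete pairs; r2 undefined, returning 0")
        return 0.0
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _dataset_minor_alleles(dataset: GenotypeDataset, snp_ids) -> dict:
    """Minor allele per SNP recomputed on *this* dataset's samples."""
    cols = dataset.snp_index(snp_ids)
    freq = dataset.minor_allele_frequency()[cols]
    out = {}
    for s, j, f in zip(snp_ids, cols, freq):
        counted = dataset.counted_allele[j]
        other = (
            dataset.allele2[j]
            if dataset.allele1[j] == counted
            else dataset.allele1[j]
        )
        out[s] = counted if (np.isnan(f) or f <= 0.5) else other
    return out


def build_ld_blocks(
    dataset: GenotypeDataset,
    selected_snp_ids,
    r2_threshold: float,
    selection_k: int = 500,
    linkage: str = "complete",
) -> BlockSchema:
    """Greedy left-to-right block construction over the selected SNPs.

    Per chromosome, in position order among the *selected* SNPs, a block
    grows while the next SNP has r2 >= threshold with every current
    member (complete linkage; ``linkage='single'`` checks only the last
    member).  Singleton blocks are demoted to covariates.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    if linkage not in ("complete", "single"):
        raise ValueError("linkage must be 'complete' or 'single'")
    cols = dataset.snp_index(selected_snp_ids)
    order = np.lexsort((dataset.pos[cols], dataset.chrom[cols].astype(str)))
    snps = [selected_snp_ids[i] for i in order]
    cols = cols[order]
    chroms = dataset.chrom[cols].astype(str)

    blocks, covariates = [], []
    dosage = dataset.dosage
    i, counter = 0, 0
    while i < len(snps):
        members = [i]
        j = i + 1
        while j < len(snps) and chroms[j] == chroms[i]:
            cand = dosage[:, cols[j]]
            check = members if linkage == "complete" else members[-1:]
            if all(
                genotype_r2(dosage[:, cols[m]], cand) >= r2_threshold
                for m in check
            ):
                members.append(j)
                j += 1
            else:
                break
        if len(members) >= 2:
            counter += 1
            blocks.append(
                Block(
                    id=f"b{counter:03d}",
                    chrom=str(chroms[i]),
                    snp_ids=tuple(snps[m] for m in members),
                )
            )
        else:
            covariates.append(snps[i])
        i = members[-1] + 1

    prov = hashlib.sha1(
        ("|".join(dataset.sample_ids) + f"|r2={r2_threshold}").encode()
    ).hexdigest()[:12]
    return BlockSchema(
        blocks=blocks,
        covariates=covariates,
        minor_alleles=_dataset_minor_alleles(dataset, snps),
        r2_threshold=r2_threshold,
        selection_k=selection_k,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Applying a schema
# ---------------------------------------------------------------------------

@dataclass
class BlockData:
    """Schema applied to a dataset: per-block counts and covariates.

    block_counts : (n_samples, n_blocks, 3) genotype-state counts; the
        per-individual row sum is that individual's nrep for the block
        (missing SNPs shrink it).
    """

    block_ids: list
    block_counts: np.ndarray
    covariate_ids: list
    covariate_dosage: np.ndarray  # (n_samples, n_cov), schema-coded


def _recode_to_schema(schema: BlockSchema, dataset: GenotypeDataset, snp_ids):
    """Dosage columns re-coded to the schema's minor-allele definitions."""
    try:
        cols = dataset.snp_index(snp_ids)
    except KeyError as e:
        raise KeyError(f"schema SNP absent from dataset: {e}") from e
    d = dataset.dosage[:, cols].astype(np.int8)
    for out_j, (s, j) in enumerate(zip(snp_ids, cols)):
        want = schema.minor_alleles.get(s, dataset.counted_allele[j])
        if want == dataset.counted_allele[j]:
            continue
        if want not in (dataset.allele1[j], dataset.allele2[j]):
            raise ValueError(
                f"schema minor allele {want!r} for SNP {s} not among dataset "
                f"alleles {dataset.allele1[j]!r}/{dataset.allele2[j]!r}"
            )
        col = d[:, out_j]
        d[:, out_j] = np.where(col == MISSING, MISSING, 2 - col)
    return d


def apply_schema(schema: BlockSchema, dataset: GenotypeDataset) -> BlockData:
    """Compute per-individual block counts and covariate dosages.

    Minor-allele definitions come from the schema (learned on the
    screening set), never recomputed, so a replication set with flipped
    allele frequencies is still counted on the screening-set coding.
    """
    n = dataset.n_samples
    counts = np.zeros((n, len(schema.blocks), N_STATES), dtype=np.int16)
    for b_idx, block in enumerate(schema.blocks):
        d = _recode_to_schema(schema, dataset, list(block.snp_ids))
        for s in range(N_STATES):
            counts[:, b_idx, s] = (d == s).sum(axis=1)
    if schema.covariates:
        cov = _recode_to_schema(schema, dataset, list(schema.covariates))
    else:
        cov = np.zeros((n, 0), dtype=np.int8)
    return BlockData(
        block_ids=[b.id for b in schema.blocks],
        block_counts=counts,
        covariate_ids=list(schema.covariates),
        covariate_dosage=cov,
    )
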