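"""Genotype containers and PLINK text (.ped/.map) input/output.

Genotypes are stored as minor-allele dosage (0/1/2 copies of the SNP's
minor allele), with ``-1`` marking a missing genotype.  The minor allele
is determined when the data are loaded and recorded per SNP, so that the
coding can be transferred (and, where needed, flipped) to a replication
set via a :class:`~hnbgwas.ld.BlockSchema`.

Phenotypes follow the PLINK convention: 1 = control, 2 = case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
CONTROL, CASE = 1, 2


@dataclass
class GenotypeDataset:
    """Samples x SNPs dosage matrix with SNP metadata and phenotypes.

    Attributes
    ----------
    sample_ids : list of str
    labels : (n_samples,) int array with values in {1 (control), 2 (case)}
    snp_ids : list of str
    chrom : (n_snps,) array of chromosome labels (compared as strings)
    pos : (n_snps,) int array of 1-based positions
    allele1, allele2 : per-SNP allele letters
    counted_allele : per-SNP allele whose copies the dosage counts
        (the minor allele at load time)
    dosage : (n_samples, n_snps) int8 array in {0, 1, 2, -1}
    """

    sample_ids: list
    labels: np.ndarray
    snp_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    counted_allele: np.ndarray
    dosage: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be 0/1/2 or -1 (missing)")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    # -- basic container behaviour -------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def snp_index(self, snp_ids) -> np.ndarray:
        """Column indices of ``snp_ids``; raises naming unknown ids."""
        missing = [s for s in snp_ids if s not in self._index]
        if missing:
            raise KeyError(f"unknown SNP id(s): {missing[:10]}")
        return np.array([self._index[s] for s in snp_ids], dtype=int)

    def subset_samples(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            dosage=self.dosage[idx],
        )

    def subset_snps(self, snp_ids) -> "GenotypeDataset":
        j = self.snp_index(snp_ids)
        return replace(
            self,
            snp_ids=list(snp_ids),
            chrom=self.chrom[j],
            pos=self.pos[j],
            allele1=self.allele1[j],
            allele2=self.allele2[j],
            counted_allele=self.counted_allele[j],
            dosage=self.dosage[:, j],
        )

    def sort_by_position(self) -> "GenotypeDataset":
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.subset_snps([self.snp_ids[i] for i in order])

    # -- derived quantities --------------------------------------------
    def minor_allele_frequency(self) -> np.ndarray:
        """Frequency of the counted (minor-at-load) allele per SNP."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        return np.asarray(d.mean(axis=0).filled(np.nan)) / 2.0

    def missingness(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def genotype_counts(self, mask=None) -> np.ndarray:
        """(n_snps, 3) counts of dosage states over ``mask`` samples."""
        d = self.dosage if mask is None else self.dosage[mask]
        return np.stack([(d == s).sum(axis=0) for s in (0, 1, 2)], axis=1)


def _minor_allele(a1_col: np.ndarray, a2_col: np.ndarray) -> tuple:
    """Minor allele from two allele-call columns ('0' = missing)."""
    calls = np.concatenate([a1_col, a2_col])
    calls = calls[calls != "0"]
    alleles, counts = np.unique(calls, return_counts=True)
    if len(alleles) > 2:
        raise ValueError(f"non-biallelic SNP with alleles {list(alleles)}")
    if len(alleles) == 0:
        return "0", "0"
    if len(alleles) == 1:
        return alleles[0], alleles[0]
    # tie -> lexicographically smaller allele counted, for determinism
    if counts[0] == counts[1]:
        minor = min(alleles)
    else:
        minor = alleles[np.argmin(counts)]
    major = alleles[0] if alleles[1] == minor else alleles[1]
    return minor, major


def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read a PLINK text pedigree (.ped) and marker map (.map) file pair.

    '0 0' allele pairs become missing genotypes; dosages are coded to the
    minor allele computed over the loaded samples; SNPs are sorted by
    (chromosome, position) after loading.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str, "snp": str},
    )
    if mp["snp"].duplicated().any():
        dups = mp.loc[mp["snp"].duplicated(), "snp"].tolist()
        raise ValueError(f"duplicate SNP id(s) in {map_path}: {dups[:10]}")
    n_snps = len(mp)

    sample_ids, labels, rows_a1, rows_a2 = [], [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} SNPs, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            labels.append(int(parts[5]))
            alle = parts[6:]
            rows_a1.append(alle[0::2])
            rows_a2.append(alle[1::2])
    if not sample_ids:
        raise ValueError(f"{ped_path}: no samples")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{ped_path}: duplicate sample ids")
    a1 = np.array(rows_a1, dtype=object)
    a2 = np.array(rows_a2, dtype=object)

    minor = np.empty(n_snps, dtype=object)
    dosage = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    alle1 = np.empty(n_snps, dtype=object)
    alle2 = np.empty(n_snps, dtype=object)
    for j in range(n_snps):
        try:
            mnr, mjr = _minor_allele(a1[:, j], a2[:, j])
        except ValueError as e:
            raise ValueError(f"{map_path}: SNP {mp['snp'][j]}: {e}") from e
        minor[j] = mnr
        alle1[j], alle2[j] = mnr, mjr
        obs = (a1[:, j] != "0") & (a2[:, j] != "0")
        dosage[obs, j] = (a1[obs, j] == mnr).astype(np.int8) + (
            a2[obs, j] == mnr
        ).astype(np.int8)

    ds = GenotypeDataset(
        sample_ids=sample_ids,
        labels=np.array(labels),
        snp_ids=mp["snp"].tolist(),
        chrom=mp["chrom"].to_numpy(dtype=object),
        pos=mp["pos"].to_numpy(),
        allele1=alle1,
        allele2=alle2,
        counted_allele=minor,
        dosage=dosage,
    )
    return ds.sort_by_position()


def write_plink_text(ds: GenotypeDataset, ped_path, map_path, pheno_path=None):
    """Write a dataset as PLINK text .ped/.map (+ optional phenotype TSV)."""
    with open(map_path, "w") as fh:
        for j in range(ds.n_snps):
            fh.write(f"{ds.chrom[j]}\t{ds.snp_ids[j]}\t0\t{ds.pos[j]}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.sample_ids):
            fields = [sid, sid, "0", "0", "0", str(int(ds.labels[i]))]
            row = ds.dosage[i]
            for j in range(ds.n_snps):
                d = row[j]
                mnr, other = ds.counted_allele[j], (
                    ds.allele2[j]
                    if ds.allele1[j] == ds.counted_allele[j]
                    else ds.allele1[j]
                )
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [other, other]
                elif d == 1:
                    fields += [mnr, other]
                else:
                    fields += [mnr, mnr]
            fh.write(" ".join(fields) + "\n")
    if pheno_path is not None:
        pd.DataFrame({"id": ds.sample_ids, "label": ds.labels}).to_csv(
            pheno_path, sep="\t", index=False
        )
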