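"""Genotype container, QC, marker codings and genomic relationship matrices.

Genotypes are stored as allele-B dosages in {0, 1, 2} (NaN = missing call)
for individuals labelled by population (two pure lines and their F1).
Allele B is defined once, globally — the VCF ALT allele or the counted
allele of a coded matrix — and is the same allele in all three
populations, so that cross-population frequency contrasts are coherent.

The additive coding Z maps genotypes BB, Bb, bb to 1, 0, -1 and the
dominance coding W maps them to 0, 1, 0 (no allele-frequency centering).
The genomic additive and dominance relationship matrices are the
trace-normalized cross-products

    G = ZZ' / (tr[ZZ']/n),    D = WW' / (tr[WW']/n),

whose diagonals average exactly 1; the scale factors tZ = tr[ZZ']/n and
tW = tr[WW']/n convert between the covariance components of the GBLUP
model and per-SNP variances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrices",
    "qc_filter",
    "allele_freqs",
    "code_additive",
    "code_dominance",
    "normalized_grm",
    "normalized_drm",
    "homozygosity",
    "build_relationships",
    "read_coded_matrix",
    "write_coded_matrix",
    "read_vcf",
    "write_relationships",
    "read_relationships",
    "GenotypeQC",
]


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-B dosages with population labels.

    ``dosages`` is a float array with entries in {0, 1, 2} or NaN for a
    missing call.  ``pop_labels`` assigns each individual to exactly one
    population (e.g. "P1", "P2", "F1").
    """

    dosages: np.ndarray
    pop_labels: np.ndarray
    individual_ids: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        n, m = self.dosages.shape
        if len(self.pop_labels) != n or len(self.individual_ids) != n:
            raise ValueError("individual annotations do not match dosage rows")
        if len(self.marker_ids) != m:
            raise ValueError("marker_ids do not match dosage columns")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker_ids must be unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list:
        """Population labels in order of first appearance."""
        return list(pd.unique(self.pop_labels))

    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        """Return a copy restricted to boolean/index arrays of rows/columns."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        mrk = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        if mrk.dtype == bool:
            mrk = np.flatnonzero(mrk)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(ind, mrk)].copy(),
            pop_labels=self.pop_labels[ind].copy(),
            individual_ids=self.individual_ids[ind].copy(),
            marker_ids=self.marker_ids[mrk].copy(),
        )


@dataclass
class RelationshipMatrices:
    """Trace-normalized genomic additive (G) and dominance (D) matrices
    with their scale factors tZ = tr[ZZ']/n and tW = tr[WW']/n."""

    G: np.ndarray
    D: np.ndarray
    tZ: float
    tW: float
    individual_ids: np.ndarray
    pop_labels: np.ndarray
    n_markers: int


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    snp_call_min: float = 0.90,
    ind_call_min: float = 0.90,
) -> GenotypeMatrix:
    """Quality control: drop low-MAF and low-call-rate SNPs, then
    low-call-rate individuals.

    MAF and SNP call rate are computed in the overall (pooled) population.
    Order: MAF filter, then SNP call-rate filter, then individual
    call-rate filter, each on the then-current panel.
    """
    for name, v in (("maf_min", maf_min), ("snp_call_min", snp_call_min),
                    ("ind_call_min", ind_call_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    dos = geno.dosages
    obs = ~np.isnan(dos)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * obs.sum(axis=0))
    maf = np.minimum(p, 1.0 - p)
    keep_snp = np.nan_to_num(maf, nan=-1.0) >= maf_min
    geno = geno.subset(markers=keep_snp)

    obs = ~np.isnan(geno.dosages)
    snp_rate = obs.mean(axis=0) if geno.n_individuals else np.zeros(geno.n_markers)
    geno = geno.subset(markers=snp_rate >= snp_call_min)

    obs = ~np.isnan(geno.dosages)
    ind_rate = obs.mean(axis=1) if geno.n_markers else np.zeros(geno.n_individuals)
    geno = geno.subset(individuals=ind_rate >= ind_call_min)

    if geno.n_individuals == 0 or geno.n_markers == 0:
        raise ValueError("QC removed all individuals or all markers")
    return geno


def allele_freqs(geno: GenotypeMatrix) -> pd.DataFrame:
    """Observed allele-B frequency per marker per population.

    Missing calls are ignored; a (population, marker) cell with zero
    observed calls is NaN.
    """
    rows = {}
    for pop in geno.populations:
        sub = geno.dosages[geno.pop_labels == pop]
        n_obs = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            rows[pop] = np.nansum(sub, axis=0) / (2.0 * n_obs)
    return pd.DataFrame.from_dict(rows, orient="index", columns=geno.marker_ids)


def _impute_freqs(geno: GenotypeMatrix, freqs: pd.DataFrame | None) -> np.ndarray:
    """Per-individual allele frequency row (own population's frequency,
    overall frequency as fallback where a population has no calls)."""
    if freqs is None:
        freqs = allele_freqs(geno)
    overall_obs = ~np.isnan(geno.dosages)
    with np.errstate(invalid="ignore"):
        overall = np.nansum(geno.dosages, axis=0) / (2.0 * overall_obs.sum(axis=0))
    out = np.empty_like(geno.dosages)
    for pop in geno.populations:
        pf = freqs.loc[pop].to_numpy(dtype=float)
        pf = np.where(np.isnan(pf), overall, pf)
        out[geno.pop_labels == pop] = pf
    return out


def code_additive(geno: GenotypeMatrix, freqs: pd.DataFrame | None = None) -> np.ndarray:
    """Additive coding Z: genotype BB -> 1, Bb -> 0, bb -> -1.

    Missing calls are mean-imputed from the individual's own population's
    allele frequency p as 2p - 1.  No frequency centering is applied.
    """
    Z = geno.dosages - 1.0
    miss = np.isnan(Z)
    if miss.any():
        p = _impute_freqs(geno, freqs)
        Z[miss] = (2.0 * p - 1.0)[miss]
    return Z


def code_dominance(geno: GenotypeMatrix, freqs: pd.DataFrame | None = None) -> np.ndarray:
    """Dominance coding W: BB -> 0, Bb -> 1, bb -> 0.

    Missing calls are imputed by the expected heterozygosity 2p(1-p) of
    the individual's own population.
    """
    W = np.where(geno.dosages == 1.0, 1.0, 0.0)
    miss = np.isnan(geno.dosages)
    if miss.any():
        p = _impute_freqs(geno, freqs)
        W[miss] = (2.0 * p * (1.0 - p))[miss]
    return W


def _normalized_crossproduct(M: np.ndarray) -> tuple[np.ndarray, float]:
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    cross = M @ M.T
    t = float(np.trace(cross)) / n
    if t <= 0.0:
        raise ValueError("zero trace: all coded values vanish")
    return cross / t, t

def normalized_grm(Z: np.ndarray) -> tuple[np.ndarray, float]:
    """G = ZZ'/tZ with tZ = tr[ZZ']/n, so mean(diag(G)) = 1."""
    return _normalized_crossproduct(np.asarray(Z, dtype=float))

def normalized_drm(W: np.ndarray) -> tuple[np.ndarray, float]:
    """D = WW'/tW with tW = tr[WW']/n, so mean(diag(D)) = 1."""
    return _normalized_crossproduct(np.asarray(W, dtype=float))


def homozygosity(geno: GenotypeMatrix) -> np.ndarray:
    """Within-individual genomic homozygosity F_Ho.

    F_Ho = (N_AA + N_aa) / (N_AA + N_Aa + N_aa) over observed calls.
    """
    obs = ~np.isnan(geno.dosages)
    n_obs = obs.sum(axis=1)
    if np.any(n_obs == 0):
        bad = geno.individual_ids[n_obs == 0]
        raise ValueError(f"individuals with zero observed calls: {list(bad)}")
    hom = ((geno.dosages == 0.0) | (geno.dosages == 2.0)).sum(axis=1)
    return hom / n_obs


def build_relationships(geno: GenotypeMatrix) -> RelationshipMatrices:
    """Code the panel and build one joint G and D over all individuals.

    A single G (and D) is built over all genotyped individuals jointly and
    normalized by the overall trace: the multi-population GBLUP covariance
    Var(u*) = G_o (x) G presumes one shared relationship matrix.
    """
    freqs = allele_freqs(geno)
    Z = code_additive(geno, freqs)
    W = code_dominance(geno, freqs)
    G, tZ = normalized_grm(Z)
    D, tW = normalized_drm(W)
    return RelationshipMatrices(
        G=G, D=D, tZ=tZ, tW=tW,
        individual_ids=geno.individual_ids.copy(),
        pop_labels=geno.pop_labels.copy(),
        n_markers=geno.n_markers,
    )


# ---------------------------------------------------------------------------
# text I/O

def write_coded_matrix(geno: GenotypeMatrix, path) -> None:
    """Write the coded-matrix format: tab-separated, header of marker ids,
    one row per individual (id, population, dosages with NA missing)."""
    with open(path, "w") as fh:
        fh.write("individual_id\tpopulation\t" + "\t".join(map(str, geno.marker_ids)) + "\n")
        for i in range(geno.n_individuals):
            row = [
                "NA" if np.isnan(v) else str(int(v)) for v in geno.dosages[i]
            ]
            fh.write(f"{geno.individual_ids[i]}\t{geno.pop_labels[i]}\t" + "\t".join(row) + "\n")


def read_coded_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "population": str},
                     na_values=["NA"])
    if df.columns[0] != "individual_id" or df.columns[1] != "population":
        raise ValueError("coded matrix must start with individual_id and population columns")
    return GenotypeMatrix(
        dosages=df.iloc[:, 2:].to_numpy(dtype=float),
        pop_labels=df["population"].to_numpy(),
        individual_ids=df["individual_id"].to_numpy(),
        marker_ids=df.columns[2:].to_numpy(),
    )


def read_vcf(path, populations) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; dosage counts the ALT allele.

    ``populations`` maps sample id -> population label (dict or a
    two-column whitespace-delimited file).  Multi-allelic records are
    rejected.
    """
    from cyvcf2 import VCF

    if not isinstance(populations, dict):
        pop_df = pd.read_csv(populations, sep=r"\s+", header=None, dtype=str)
        populations = dict(zip(pop_df[0], pop_df[1]))
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in populations]
    if missing:
        raise ValueError(f"samples without a population label: {missing}")
    cols, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown? see below
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        dos = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols.append(dos)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if not cols:
        raise ValueError("no variants in VCF")
    return GenotypeMatrix(
        dosages=np.column_stack(cols),
        pop_labels=np.array([populations[s] for s in samples], dtype=object),
        individual_ids=np.array(samples, dtype=object),
        marker_ids=np.array(ids, dtype=object),
    )


def write_relationships(rel: RelationshipMatrices, prefix) -> None:
    """Write G and D as 1-based 'i j value' upper-triangle triplets
    (<prefix>.G.txt, <prefix>.D.txt) plus a JSON sidecar with tZ, tW, n,
    ids and population labels."""
    for mat, tag in ((rel.G, "G"), (rel.D, "D")):
        with open(f"{prefix}.{tag}.txt", "w") as fh:
            n = mat.shape[0]
            for i in range(n):
                for j in range(i, n):
                    fh.write(f"{i + 1} {j + 1} {mat[i, j]:.12g}\n")
    meta = {
        "tZ": rel.tZ,
        "tW": rel.tW,
        "n": int(len(rel.individual_ids)),
        "n_markers": int(rel.n_markers),
        "individual_ids": [str(x) for x in rel.individual_ids],
        "pop_labels": [str(x) for x in rel.pop_labels],
    }
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_relationships(prefix) -> RelationshipMatrices:
    with open(f"{prefix}.meta.json") as fh:
        meta = json.load(fh)
    n = meta["n"]
    mats = {}
    for tag in ("G", "D"):
        M = np.zeros((n, n))
        with open(f"{prefix}.{tag}.txt") as fh:
            for line in fh:
                i, j, v = line.split()
                M[int(i) - 1, int(j) - 1] = float(v)
                M[int(j) - 1, int(i) - 1] = float(v)
        mats[tag] = M
    return RelationshipMatrices(
        G=mats["G"], D=mats["D"], tZ=meta["tZ"], tW=meta["tW"],
        individual_ids=np.array(meta["individual_ids"], dtype=object),
        pop_labels=np.array(meta["pop_labels"], dtype=object),
        n_markers=meta["n_markers"],
    )


class GenotypeQC(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer applying the panel QC filters.

    Parameters mirror :func:`qc_filter`; ``fit`` records which markers and
    individuals survive, ``transform`` subsets a GenotypeMatrix.
    """

    def __init__(self, maf_min: float = 0.05, snp_call_min: float = 0.90,
                 ind_call_min: float = 0.90):
        self.maf_min = maf_min
        self.snp_call_min = snp_call_min
        self.ind_call_min = ind_call_min

    def fit(self, X: GenotypeMatrix, y=None):
        filtered = qc_filter(X, self.maf_min, self.snp_call_min, self.ind_call_min)
        self.kept_markers_ = filtered.marker_ids
        self.kept_individuals_ = filtered.individual_ids
        self.n_markers_in_ = X.n_markers
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        keep_m = np.isin(X.marker_ids.astype(str), self.kept_markers_.astype(str))
        keep_i = np.isin(X.individual_ids.astype(str), self.kept_individuals_.astype(str))
        return X.subset(individuals=keep_i, markers=keep_m)
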