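"""Genotype handling for risk-carrier moderator construction.

Biallelic SNP genotypes are represented as risk-allele dosages (0, 1, 2,
or missing).  The module provides Hardy-Weinberg conformance testing,
pairwise linkage disequilibrium (D', r-squared), EM estimation of
haplotype frequencies from unphased genotypes with posterior diplotype
assignment, and construction of the binary moderator groups used in the
moderated regressions: dominant coding for single SNPs (non-risk
homozygotes vs carriers of at least one risk allele) and carrier coding
for a risk haplotype against a reference haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptySNPError, MonomorphicLocusError

_VALID_ALLELES = frozenset("ACGT")
_MISSING_TOKENS = {"", "NA", "NAN", "N/A", ".", "./.", "-", "NONE"}


@dataclass(frozen=True)
class SNPDef:
    """A biallelic SNP with declared risk and non-risk alleles."""

    rsid: str
    non_risk_allele: str
    risk_allele: str

    def __post_init__(self) -> None:
        for allele in (self.non_risk_allele, self.risk_allele):
            if allele not in _VALID_ALLELES:
                raise ValueError(
                    f"{self.rsid}: allele {allele!r} is not one of A, C, G, T"
                )
        if self.non_risk_allele == self.risk_allele:
            raise ValueError(f"{self.rsid}: risk and non-risk alleles must differ")


class GenotypeTable:
    """Per-individual risk-allele dosages for a set of named SNPs.

    Parameters
    ----------
    dosages
        DataFrame indexed by individual id with one column per rsID.
        Values must be 0, 1, 2 or NaN (missing).
    snps
        ``SNPDef`` objects covering every column of ``dosages``.
    """

    def __init__(self, dosages: pd.DataFrame, snps: Sequence[SNPDef]):
        snp_map = {s.rsid: s for s in snps}
        unknown = [c for c in dosages.columns if c not in snp_map]
        if unknown:
            raise ValueError(f"no SNP definition for column(s): {unknown}")
        values = dosages.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")
        self.dosages = dosages.astype(float)
        self.snps: dict[str, SNPDef] = {r: snp_map[r] for r in dosages.columns}

    # -- basic accessors -------------------------------------------------
    @property
    def individual_ids(self) -> list:
        return list(self.dosages.index)

    @property
    def rsids(self) -> list[str]:
        return list(self.dosages.columns)

    def __len__(self) -> int:
        return len(self.dosages)

    def dosage(self, rsid: str) -> pd.Series:
        if rsid not in self.dosages.columns:
            raise KeyError(f"genotype table does not contain {rsid}")
        return self.dosages[rsid]

    def genotype_counts(self, rsid: str) -> np.ndarray:
        """Counts of (non-risk hom, het, risk hom), ignoring missing calls."""
        d = self.dosage(rsid).dropna().to_numpy()
        return np.array([(d == k).sum() for k in (0, 1, 2)], dtype=int)

    def subset(self, rsids: Sequence[str]) -> "GenotypeTable":
        return GenotypeTable(self.dosages[list(rsids)], [self.snps[r] for r in rsids])

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, snps: Sequence[SNPDef], id_column: str | None = None):
        """Read a genotype CSV/TSV.

        First column (or ``id_column``) holds individual ids; remaining
        columns are rsIDs.  Cells may be allele pairs ("A/C") or dosages
        (0/1/2); the format is auto-detected per cell.  Columns without a
        SNP definition are ignored.
        """
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
        if raw.shape[1] < 2:
            raise ValueError(f"{path}: expected an id column plus genotype columns")
        id_col = id_column or raw.columns[0]
        raw = raw.set_index(id_col)
        snp_map = {s.rsid: s for s in snps}
        cols = {}
        for rsid in raw.columns:
            if rsid not in snp_map:
                continue
            cols[rsid] = raw[rsid].map(lambda v: _parse_genotype(v, snp_map[rsid]))
        if not cols:
            raise ValueError(f"{path}: no declared SNP columns found")
        frame = pd.DataFrame(cols, index=raw.index)
        return cls(frame, snps)

    @classmethod
    def from_vcf(cls, path, snps: Sequence[SNPDef]):
        """Read biallelic SNP records (GT field only) from a VCF file.

        REF/ALT are mapped to the declared risk allele; a record whose
        alleles do not match the declaration raises, rather than guessing
        strand.  Requires the optional :mod:`cyvcf2` dependency.
        """
        from cyvcf2 import VCF

        defs = {s.rsid: s for s in snps}
        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        data: dict[str, np.ndarray] = {}
        for var in vcf:
            d = defs.get(var.ID)
            if d is None:
                continue
            if len(var.ALT) != 1:
                raise ValueError(f"{var.ID}: only biallelic records are supported")
            ref, alt = var.REF.upper(), var.ALT[0].upper()
            if {ref, alt} != {d.non_risk_allele, d.risk_allele}:
                raise ValueError(
                    f"{var.ID}: VCF alleles {ref}/{alt} do not match the declared "
                    f"{d.non_risk_allele}/{d.risk_allele} (possible strand mismatch)"
                )
            gt = var.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing
            gt[gt == 3] = np.nan
            data[var.ID] = gt if alt == d.risk_allele else 2.0 - gt
        frame = pd.DataFrame(data, index=samples)
        return cls(frame, [defs[r] for r in frame.columns])

    def to_csv(self, path) -> None:
        out = self.dosages.copy()
        out.index.name = out.index.name or "individual_id"
        out.to_csv(path, float_format="%g")


def _parse_genotype(value, snp: SNPDef) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    token = str(value).strip().upper()
    if token in _MISSING_TOKENS:
        return np.nan
    if "/" in token or "|" in token:
        sep = "/" if "/" in token else "|"
        alleles = token.split(sep)
        if len(alleles) != 2:
            raise ValueError(f"{snp.rsid}: cannot parse genotype {value!r}")
        dosage = 0.0
        for a in alleles:
            if a == snp.risk_allele:
                dosage += 1
            elif a != snp.non_risk_allele:
                raise ValueError(
                    f"{snp.rsid}: allele {a!r} is neither the declared risk "
                    f"({snp.risk_allele}) nor non-risk ({snp.non_risk_allele}) allele"
                )
        return dosage
    dosage = float(token)
    if dosage not in (0.0, 1.0, 2.0):
        raise ValueError(f"{snp.rsid}: dosage {value!r} not in {{0, 1, 2}}")
    return dosage


# ---------------------------------------------------------------------------
# Allele frequencies and Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def allele_frequency(genotype_counts) -> float:
    """Frequency of the non-risk allele from (non-risk hom, het, risk hom) counts."""
    c = np.asarray(genotype_counts, dtype=float)
    if c.shape != (3,):
        raise ValueError("genotype_counts must be three numbers")
    total = c.sum()
    if total <= 0:
        raise EmptySNPError("no called genotypes for this SNP")
    return float((2 * c[0] + c[1]) / (2 * total))


@dataclass(frozen=True)
class HWEResult:
    """Chi-square test (1 df, no continuity correction) of HWE conformance."""

    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    p_value: float
    monomorphic: bool = False


def hwe_test(genotype_counts) -> HWEResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    Expected counts are p^2, 2pq, q^2 times the total, with p estimated
    from the observed allele frequency; the statistic has one degree of
    freedom.  A monomorphic SNP is degenerate: chi2 = 0, p = 1, flagged.
    """
    observed = np.asarray(genotype_counts, dtype=float)
    p = allele_frequency(observed)  # validates shape and total
    total = observed.sum()
    q = 1.0 - p
    expected = total * np.array([p * p, 2 * p * q, q * q])
    if p == 0.0 or p == 1.0:
        return HWEResult(observed, expected, 0.0, 1.0, monomorphic=True)
    chi2 = float((np.square(observed - expected) / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(observed, expected, chi2, p_value)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage disequilibrium between two biallelic loci."""

    d: float
    d_prime: float
    r_squared: float


def ld_pairwise(haplotype_freqs: Mapping[str, float]) -> LDStats:
    """D, D' and r^2 from two-locus haplotype frequencies.

    ``haplotype_freqs`` maps two-character allele strings (first locus,
    second locus) to frequencies summing to one.  Missing combinations
    count as frequency zero.  Both measures are invariant to allele
    relabelling.  A fixed marginal raises :class:`MonomorphicLocusError`
    because LD is then undefined (not merely zero).
    """
    keys = list(haplotype_freqs)
    if any(len(k) != 2 for k in keys):
        raise ValueError("haplotype keys must be two-character allele strings")
    freqs = {k: float(v) for k, v in haplotype_freqs.items()}
    if any(v < -1e-12 for v in freqs.values()):
        raise ValueError("haplotype frequencies must be non-negative")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"haplotype frequencies sum to {total}, expected 1")
    alleles_1 = sorted({k[0] for k in keys})
    alleles_2 = sorted({k[1] for k in keys})
    if len(alleles_1) > 2 or len(alleles_2) > 2:
        raise ValueError("ld_pairwise handles biallelic loci only")
    if len(alleles_1) < 2 or len(alleles_2) < 2:
        raise MonomorphicLocusError("a locus is monomorphic; LD is undefined")
    a, b = alleles_1[0], alleles_2[0]
    p_a = sum(v for k, v in freqs.items() if k[0] == a)
    p_b = sum(v for k, v in freqs.items() if k[1] == b)
    if min(p_a, 1 - p_a, p_b, 1 - p_b) <= 0:
        raise MonomorphicLocusError("a locus is monomorphic; LD is undefined")
    p_ab = freqs.get(a + b, 0.0)
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d == 0 else min(abs(d) / d_max, 1.0)
    r_squared = min(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)), 1.0)
    return LDStats(d=float(d), d_prime=float(d_prime), r_squared=float(r_squared))


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeEstimate:
    """Maximum-likelihood haplotype frequencies and argmax diplotypes.

    ``diplotypes`` has one row per individual with complete genotypes:
    columns ``hap1``, ``hap2`` (allele strings, lexicographically ordered)
    and ``posterior`` (probability of that phase given the estimated
    frequencies).  ``loglik_trace`` is the per-iteration log-likelihood of
    the best EM start; it is non-decreasing by construction.
    """

    frequencies: dict[str, float]
    diplotypes: pd.DataFrame
    log_likelihood: float
    converged: bool
    n_iter: int
    n_used: int
    excluded_ids: list = field(default_factory=list)
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def marginal_pair_frequencies(self, rsid_i: str, rsid_j: str) -> dict[str, float]:
        """Two-locus haplotype frequencies obtained by marginalizing."""
        order = list(self.rsids)
        i, j = order.index(rsid_i), order.index(rsid_j)
        out: dict[str, float] = {}
        for hap, f in self.frequencies.items():
            key = hap[i] + hap[j]
            out[key] = out.get(key, 0.0) + f
        return out

    @property
    def rsids(self) -> list[str]:
        return list(self._rsids)


def em_haplotype_frequencies(
    genotypes: GenotypeTable,
    rsids: Sequence[str] | None = None,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 10,
    seed: int = 0,
) -> HaplotypeEstimate:
    """EM estimation of haplotype frequencies from unphased genotypes.

    Maximizes the multinomial likelihood under random union of haplotypes
    (Hardy-Weinberg at the haplotype level).  Runs one uniform start plus
    ``n_restarts`` seeded Dirichlet restarts and keeps the highest
    likelihood.  Individuals with any missing genotype at the requested
    SNPs are excluded listwise.  Diplotypes are assigned by posterior
    argmax, ties broken lexicographically by haplotype string.
    """
    rsids = list(rsids) if rsids is not None else genotypes.rsids
    k = len(rsids)
    if k < 1:
        raise ValueError("need at least one SNP")
    sub = genotypes.dosages[rsids]
    complete = sub.dropna()
    excluded = [i for i in sub.index if i not in complete.index]
    if complete.empty:
        raise EmptySNPError("no individual with complete genotypes at these SNPs")
    g = complete.to_numpy(dtype=int)
    n = len(g)

    n_hap = 1 << k
    bits = np.array(
        [[(h >> (k - 1 - j)) & 1 for j in range(k)] for h in range(n_hap)], dtype=int
    )
    defs = [genotypes.snps[r] for r in rsids]
    strings = [
        "".join(d.risk_allele if b else d.non_risk_allele for d, b in zip(defs, row))
        for row in bits
    ]

    patterns, inverse, counts = np.unique(
        g, axis=0, return_inverse=True, return_counts=True
    )
    pair_lists = []
    for pat in patterns:
        ii, jj, ww = [], [], []
        for i in range(n_hap):
            for j in range(i, n_hap):
                if np.array_equal(bits[i] + bits[j], pat):
                    ii.append(i)
                    jj.append(j)
                    ww.append(1.0 if i == j else 2.0)
        if not ii:  # unreachable for valid dosages
            raise ValueError(f"genotype pattern {pat} admits no haplotype pair")
        pair_lists.append((np.array(ii), np.array(jj), np.array(ww)))

    rng = np.random.default_rng(seed)
    starts = [np.full(n_hap, 1.0 / n_hap)]
    starts += [rng.dirichlet(np.ones(n_hap)) for _ in range(n_restarts)]

    best = None
    for f0 in starts:
        f = f0.copy()
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            loglik = 0.0
            expected = np.zeros(n_hap)
            for (ii, jj, ww), c in zip(pair_lists, counts):
                pv = ww * f[ii] * f[jj]
                s = pv.sum()
                if s <= 0.0:
                    loglik = -np.inf
                    break
                loglik += c * np.log(s)
                post = (c / s) * pv
                np.add.at(expected, ii, post)
                np.add.at(expected, jj, post)
            if not np.isfinite(loglik):
                break
            trace.append(loglik)
            f = expected / (2.0 * n)
            if len(trace) > 1 and trace[-1] - trace[-2] < tol:
                converged = True
                break
        if trace and (best is None or trace[-1] > best[0]):
            best = (trace[-1], f, np.array(trace), converged)

    if best is None:
        raise RuntimeError("EM failed on every start")
    loglik, f, trace, converged = best

    hap1, hap2, post = [], [], []
    for idx in inverse:
        ii, jj, ww = pair_lists[idx]
        pv = ww * f[ii] * f[jj]
        s = pv.sum()
        top = pv.max()
        candidates = [
            tuple(sorted((strings[i], strings[j])))
            for i, j, v in zip(ii, jj, pv)
            if v >= top - 1e-15
        ]
        h1, h2 = min(candidates)
        hap1.append(h1)
        hap2.append(h2)
        post.append(float(top / s) if s > 0 else np.nan)
    diplotypes = pd.DataFrame(
        {"hap1": hap1, "hap2": hap2, "posterior": post}, index=complete.index
    )

    est = HaplotypeEstimate(
        frequencies={s: float(v) for s, v in zip(strings, f)},
        diplotypes=diplotypes,
        log_likelihood=float(loglik),
        converged=converged,
        n_iter=len(trace),
        n_used=n,
        excluded_ids=excluded,
        loglik_trace=trace,
    )
    est._rsids = rsids
    return est


# ---------------------------------------------------------------------------
# Moderator groups
# ---------------------------------------------------------------------------

@dataclass
class ModeratorGroup:
    """Binary moderator: 0 = non-risk reference group, 1 = risk carriers."""

    coding: pd.Series
    excluded_ids: list = field(default_factory=list)
    name: str = "moderator"

    @property
    def group_sizes(self) -> tuple[int, int]:
        return int((self.coding == 0).sum()), int((self.coding == 1).sum())


def assign_snp_moderator(
    genotypes: GenotypeTable, snp: SNPDef | str, coding: str = "dominant"
) -> ModeratorGroup:
    """Dominant risk-carrier coding for a single SNP.

    0 = homozygous non-risk, 1 = carries at least one risk allele.
    Individuals with a missing genotype are excluded.
    """
    if coding != "dominant":
        raise ValueError(f"unknown coding {coding!r}; only 'dominant' is supported")
    rsid = snp.rsid if isinstance(snp, SNPDef) else snp
    d = genotypes.dosage(rsid)
    called = d.dropna()
    excluded = [i for i in d.index if i not in called.index]
    return ModeratorGroup(
        coding=(called >= 1).astype(int), excluded_ids=excluded, name=rsid
    )


def assign_haplotype_moderator(
    diplotypes: pd.DataFrame | HaplotypeEstimate,
    risk_haplotype: str = "CAT",
    reference_haplotype: str = "AGC",
    name: str = "HAPL",
) -> ModeratorGroup:
    """Risk-haplotype carrier coding.

    1 = carries >= 1 copy of the risk haplotype; 0 = carries the reference
    haplotype (and no risk copy); individuals with neither are excluded,
    mirroring the "other/other" exclusions of the comparison-group design.
    """
    if isinstance(diplotypes, HaplotypeEstimate):
        diplotypes = diplotypes.diplotypes
    is_risk = (diplotypes["hap1"] == risk_haplotype) | (
        diplotypes["hap2"] == risk_haplotype
    )
    has_ref = (diplotypes["hap1"] == reference_haplotype) | (
        diplotypes["hap2"] == reference_haplotype
    )
    keep = is_risk | has_ref
    coding = is_risk[keep].astype(int)
    excluded = [i for i in diplotypes.index if not keep.loc[i]]
    return ModeratorGroup(coding=coding, excluded_ids=excluded, name=name)
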