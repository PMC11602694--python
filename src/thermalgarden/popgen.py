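"""Microsatellite population genetics and the heterosis test.

GENEPOP I/O, per-locus diversity summaries, multi-allelic Weir–Cockerham
F_ST with permutation differentiation tests, DAPC-style clustering
(PCA → k-means with BIC model choice → discriminant axes), standardized
multilocus heterozygosity (sMLH), and the Monte-Carlo heterosis test of
individual fitness (nec-int) against sMLH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .simulate import GenotypeMatrix

__all__ = [
    "GenotypeMatrix", "FstEstimates", "DapcResult", "HeterosisResult",
    "read_genepop", "write_genepop", "diversity_summary", "wc_fst",
    "population_isolation_summary", "dapc_clusters", "compute_smlh",
    "heterosis_test",
]


# ---------------------------------------------------------------------------
# GENEPOP I/O
# ---------------------------------------------------------------------------

class GenepopParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


def read_genepop(path, population_names: list[str] | None = None) -> GenotypeMatrix:
    """Parse a GENEPOP file (2- or 3-digit diploid allele coding).

    Locus names may be one per line or comma-separated on one line.
    Populations are delimited by ``POP`` lines; missing calls are coded
    00/000.  Mixed digit widths or ragged locus counts raise
    :class:`GenepopParseError` with a line number.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be GENEPOP")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        if not chunk:
            raise GenepopParseError("empty line in locus header", i + 1)
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP delimiter found")
    if not loci:
        raise GenepopParseError("no locus names before first POP")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = -1
    digits: int | None = None
    for ln in range(i, len(lines)):
        raw = lines[ln].strip()
        if not raw:
            continue
        if raw.upper() == "POP":
            pop_idx += 1
            continue
        if "," not in raw:
            raise GenepopParseError("expected 'id , genotypes' line", ln + 1)
        ind_id, _, geno = raw.partition(",")
        ind_id = ind_id.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"{len(tokens)} genotype fields for {len(loci)} loci", ln + 1)
        calls = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopParseError(f"malformed genotype {tok!r}", ln + 1)
            w = len(tok) // 2
            if digits is None:
                digits = w
            elif digits != w:
                raise GenepopParseError(
                    f"mixed allele digit widths ({digits} then {w})", ln + 1)
            a1, a2 = int(tok[:w]), int(tok[w:])
            if (a1 == 0) != (a2 == 0):
                raise GenepopParseError(
                    f"half-missing genotype {tok!r}", ln + 1)
            calls.append((a1, a2))
        ids.append(ind_id)
        if population_names and pop_idx < len(population_names):
            pops.append(population_names[pop_idx])
        else:
            pops.append(f"Pop{pop_idx + 1}")
        rows.append(calls)
    if not rows:
        raise GenepopParseError("no individuals found")
    matrix = GenotypeMatrix(ids, pops, loci, np.array(rows, dtype=np.int64))
    all_missing = [matrix.loci[l] for l in range(matrix.n_loci)
                   if not matrix.typed_mask()[:, l].any()]
    if all_missing:
        warnings.warn(f"loci with no typed individuals: {all_missing}")
    return matrix


def write_genepop(matrix: GenotypeMatrix, path, title: str = "thermalgarden export",
                  digits: int = 3) -> None:
    """Write a GENEPOP file; lossless round-trip with :func:`read_genepop`."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if matrix.calls.max() >= 10 ** digits:
        raise ValueError(f"allele codes too large for {digits}-digit coding")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in matrix.loci:
            fh.write(locus + "\n")
        current = None
        for idx in range(matrix.n_individuals):
            pop = matrix.populations[idx]
            if pop != current:
                fh.write("POP\n")
                current = pop
            geno = " ".join(
                f"{a1:0{digits}d}{a2:0{digits}d}"
                for a1, a2 in matrix.calls[idx]
            )
            fh.write(f"{matrix.ids[idx]} , {geno}\n")


# ---------------------------------------------------------------------------
# Diversity summaries
# ---------------------------------------------------------------------------

def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def diversity_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per population × locus: n typed, Ho, unbiased He, allelic richness.

    Ho is the observed heterozygote proportion; He the unbiased expected
    heterozygosity (2n/(2n−1))(1 − Σp²); allelic richness rarefies by
    hypergeometric expectation to the smallest typed sample (in gene
    copies) across populations at that locus.  Monomorphic loci return
    He = 0.
    """
    pops = list(dict.fromkeys(matrix.populations))
    pop_arr = np.asarray(matrix.populations)
    typed = matrix.typed_mask()
    rows = []
    for l, locus in enumerate(matrix.loci):
        n_typed_by_pop = {p: int(typed[pop_arr == p, l].sum()) for p in pops}
        if min(n_typed_by_pop.values()) == 0:
            for p in pops:
                rows.append((p, locus, n_typed_by_pop[p], np.nan, np.nan, np.nan))
            continue
        g = 2 * min(n_typed_by_pop.values())  # rarefaction size, gene copies
        for p in pops:
            sel = (pop_arr == p) & typed[:, l]
            n = int(sel.sum())
            calls = matrix.calls[sel, l, :]
            ho = float((calls[:, 0] != calls[:, 1]).mean())
            alleles, counts = np.unique(calls.ravel(), return_counts=True)
            freqs = counts / counts.sum()
            he = (2 * n / (2 * n - 1)) * (1 - np.sum(freqs ** 2)) if n > 1 else np.nan
            total = counts.sum()
            with np.errstate(invalid="ignore"):
                log_absent = _log_comb(total - counts, g) - _log_comb(np.array(total, float), g)
            p_absent = np.where(total - counts >= g, np.exp(log_absent), 0.0)
            richness = float(np.sum(1.0 - p_absent))
            rows.append((p, locus, n, ho, float(he), richness))
    return pd.DataFrame(rows, columns=["population", "locus", "n_typed",
                                       "ho", "he_unbiased", "allelic_richness"])


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstEstimates:
    global_theta: float
    pairwise: pd.DataFrame        # symmetric population matrix of theta
    global_p: float
    pairwise_p: pd.DataFrame
    n_permutations: int


class _WCData:
    """Precomputed allele-dosage representation for fast θ evaluation.

    Columns are (locus, allele) pairs; ``dose`` holds 0/1/2 copies (0
    for missing calls), so θ for any assignment of individuals to
    populations reduces to a few matrix products — the permutation test
    re-evaluates θ hundreds of times.
    """

    def __init__(self, calls: np.ndarray):
        n, n_loci, _ = calls.shape
        self.typed = calls[:, :, 0] > 0
        dose_cols = []
        locus_of_col = []
        for l in range(n_loci):
            c = calls[:, l, :]
            alleles = np.unique(c[c > 0])
            for allele in alleles:
                dose_cols.append((c == allele).sum(axis=1))
            locus_of_col.extend([l] * len(alleles))
        self.dose = np.array(dose_cols, dtype=float).T     # (n, K)
        self.locus_of_col = np.array(locus_of_col)
        self.n_loci = n_loci

    def theta(self, pop_codes: np.ndarray, n_pops: int) -> float:
        """Weir–Cockerham θ = Σa / Σ(a+b+c) over loci and alleles.

        Variance components follow the multi-allelic random-population
        estimator: per allele u, with r populations of typed sizes n_i,
        allele frequencies p_i and heterozygote frequencies h_i,
        a, b and c are the among-population, among-individual and
        within-individual components.
        """
        onehot = np.zeros((len(pop_codes), n_pops))
        onehot[np.arange(len(pop_codes)), pop_codes] = 1.0
        n_il = self.typed.T.astype(float) @ onehot           # (L, r)
        valid = n_il > 0
        r_l = valid.sum(axis=1).astype(float)                # pops present
        n_l = np.where(valid, n_il, np.nan)
        nbar_l = np.nanmean(n_l, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            nc_l = (r_l * nbar_l - np.nansum(n_l ** 2, axis=1)
                    / (r_l * nbar_l)) / (r_l - 1)
        ok_l = (r_l >= 2) & (nbar_l > 1) & (nc_l > 0)

        A = onehot.T @ self.dose                             # (r, K) allele counts
        H = onehot.T @ (self.dose == 1.0)                    # (r, K) het counts
        col = self.locus_of_col
        n_rk = n_il.T[:, col]                                # (r, K)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = A / (2.0 * n_rk)
            Hf = H / n_rk
        r_c = r_l[col]
        nbar_c = nbar_l[col]
        nc_c = nc_l[col]
        w = np.where(n_rk > 0, n_rk, 0.0)
        P0 = np.where(n_rk > 0, P, 0.0)
        H0 = np.where(n_rk > 0, Hf, 0.0)
        denom = r_c * nbar_c
        pbar = (w * P0).sum(axis=0) / denom
        s2 = (w * (P0 - pbar) ** 2).sum(axis=0) / ((r_c - 1) * nbar_c)
        hbar = (w * H0).sum(axis=0) / denom
        inner = pbar * (1 - pbar) - s2 * (r_c - 1) / r_c
        a = (nbar_c / nc_c) * (s2 - (inner - hbar / 4.0) / (nbar_c - 1))
        b = (nbar_c / (nbar_c - 1)) * (inner - hbar * (2 * nbar_c - 1)
                                       / (4 * nbar_c))
        c = hbar / 2.0
        use = ok_l[col]
        num = a[use].sum()
        den = (a + b + c)[use].sum()
        if den == 0.0 or not np.isfinite(den):
            return np.nan
        return float(num / den)


def _theta(matrix_calls: np.ndarray, pop_codes: np.ndarray, n_pops: int) -> float:
    """Global Weir–Cockerham θ summing components over loci and alleles."""
    return _WCData(matrix_calls).theta(pop_codes, n_pops)


def wc_fst(matrix: GenotypeMatrix, n_permutations: int = 1000,
           seed: int | None = None) -> FstEstimates:
    """Weir–Cockerham θ (global and pairwise) with permutation tests.

    Differentiation p-values permute individuals among populations
    (same null — no genotypic differentiation — as the classical exact
    test) using the (1 + b)/(1 + n) estimator, so p is never 0.
    """
    pops = list(dict.fromkeys(matrix.populations))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    pop_codes = np.array([pops.index(p) for p in matrix.populations])
    typed = matrix.typed_mask()
    for k, p in enumerate(pops):
        if (typed[pop_codes == k].sum(axis=0) < 2).all():
            raise ValueError(f"population {p} has < 2 typed individuals "
                             "at every locus; theta undefined")
    rng = np.random.default_rng(seed)

    def _perm_p(data: _WCData, codes: np.ndarray, k: int, obs: float) -> float:
        if n_permutations <= 0 or np.isnan(obs):
            return np.nan
        hits = 0
        codes = codes.copy()
        for _ in range(n_permutations):
            rng.shuffle(codes)
            if data.theta(codes, k) >= obs:
                hits += 1
        return (1 + hits) / (1 + n_permutations)

    data = _WCData(matrix.calls)
    global_theta = data.theta(pop_codes, len(pops))
    global_p = _perm_p(data, pop_codes, len(pops), global_theta)

    pw = pd.DataFrame(np.nan, index=pops, columns=pops)
    pw_p = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sel = np.isin(pop_codes, [i, j])
            sub = _WCData(matrix.calls[sel])
            sub_codes = (pop_codes[sel] == j).astype(int)
            th = sub.theta(sub_codes, 2)
            pw.iloc[i, j] = pw.iloc[j, i] = th
            pp = _perm_p(sub, sub_codes, 2, th)
            pw_p.iloc[i, j] = pw_p.iloc[j, i] = pp
    return FstEstimates(float(global_theta), pw, float(global_p), pw_p,
                        n_permutations)


def population_isolation_summary(fst: FstEstimates) -> pd.Series:
    """Mean pairwise θ per population (leave-one-population-out view).

    A descriptive ranking of how differentiated each population is from
    the rest.  This is NOT a Bayesian site-specific F_ST (no drift model
    is fitted per site); it only orders populations by their average
    pairwise differentiation.
    """
    return fst.pairwise.mean(axis=1, skipna=True).rename("mean_pairwise_theta")


# ---------------------------------------------------------------------------
# DAPC-style clustering
# ---------------------------------------------------------------------------

@dataclass
class DapcResult:
    bic_curve: pd.Series          # K -> BIC
    chosen_k: int
    retained_pcs: int
    memberships: pd.DataFrame     # individuals x clusters, rows sum to 1
    assignments: pd.Series        # individual -> cluster label
    cluster_vs_population: pd.DataFrame  # contingency table


def allele_dosage_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Individuals × (locus, allele) dosage matrix (0/1/2).

    Missing calls are imputed to the column mean, standard practice
    before the PCA step of DAPC.
    """
    typed = matrix.typed_mask()
    cols = {}
    for l, locus in enumerate(matrix.loci):
        calls = matrix.calls[:, l, :]
        alleles = np.unique(calls[calls > 0])
        for allele in alleles:
            dose = (calls == allele).sum(axis=1).astype(float)
            dose[~typed[:, l]] = np.nan
            cols[f"{locus}.{allele}"] = dose
    df = pd.DataFrame(cols, index=matrix.ids)
    return df.fillna(df.mean())


def dapc_clusters(matrix: GenotypeMatrix, max_k: int = 3, max_pcs: int = 100,
                  n_restarts: int = 20, seed: int | None = None) -> DapcResult:
    """De-novo cluster search and discriminant analysis on genotypes.

    Centred allele-dosage PCA (up to ``max_pcs`` components), k-means
    for K = 1…max_k with multiple restarts, BIC(K) = n·log(WSS/n) +
    K·log(n) on the retained PC coordinates, then a discriminant
    analysis on those PCs for the BIC-chosen K giving per-individual
    membership probabilities.
    """
    n = matrix.n_individuals
    if max_k > n:
        raise ValueError("max_k cannot exceed the number of individuals")
    X = allele_dosage_matrix(matrix).to_numpy(float)
    X = X - X.mean(axis=0)
    n_pcs = min(max_pcs, n - 1, X.shape[1])
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(X)

    rng = np.random.default_rng(seed)
    bic = {}
    labels_by_k = {}
    for k in range(1, max_k + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=int(rng.integers(2 ** 31)))
        labels = km.fit_predict(pcs)
        wss = float(km.inertia_)
        bic[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
        labels_by_k[k] = labels
    bic_curve = pd.Series(bic, name="bic")
    chosen_k = int(bic_curve.idxmin())
    labels = labels_by_k[chosen_k]

    if chosen_k == 1:
        memberships = pd.DataFrame(
            np.ones((n, 1)), index=matrix.ids, columns=["cluster1"])
    else:
        lda = LinearDiscriminantAnalysis(
            n_components=min(chosen_k - 1, n_pcs))
        lda.fit(pcs, labels)
        proba = lda.predict_proba(pcs)
        memberships = pd.DataFrame(
            proba, index=matrix.ids,
            columns=[f"cluster{c + 1}" for c in lda.classes_])
    assignments = pd.Series(
        [f"cluster{l + 1}" for l in labels], index=matrix.ids, name="cluster")
    contingency = pd.crosstab(
        assignments, pd.Series(matrix.populations, index=matrix.ids,
                               name="population"))
    return DapcResult(bic_curve, chosen_k, n_pcs, memberships, assignments,
                      contingency)


# ---------------------------------------------------------------------------
# sMLH and heterosis
# ---------------------------------------------------------------------------

def compute_smlh(matrix: GenotypeMatrix) -> pd.Series:
    """Standardized multilocus heterozygosity per individual.

    An individual's heterozygous proportion over its typed loci, divided
    by the mean locus heterozygosity over those same loci (the expected
    proportion of a random individual typed at the same loci).  With
    complete data the mean over individuals is exactly 1.  Individuals
    typed at no locus are excluded with a warning.
    """
    typed = matrix.typed_mask()
    het = (matrix.calls[:, :, 0] != matrix.calls[:, :, 1]) & typed
    with np.errstate(invalid="ignore"):
        locus_het = np.where(typed.sum(axis=0) > 0,
                             het.sum(axis=0) / np.maximum(typed.sum(axis=0), 1),
                             np.nan)
    values = {}
    skipped = []
    for i, ind in enumerate(matrix.ids):
        s = typed[i]
        if not s.any():
            skipped.append(ind)
            continue
        num = het[i, s].mean()
        den = np.nanmean(locus_het[s])
        values[ind] = num / den if den > 0 else np.nan
    if skipped:
        warnings.warn(f"individuals typed at no locus excluded: {skipped}")
    return pd.Series(values, name="smlh")


@dataclass
class HeterosisResult:
    observed_slope: float
    null_slopes: np.ndarray
    p_value: float
    n_permutations: int
    n_individuals: int


def heterosis_test(nec_int: pd.Series, smlh: pd.Series, n_perm: int = 10000,
                   seed: int | None = None) -> HeterosisResult:
    """Monte-Carlo heterosis test: slope of nec-int on sMLH vs permutation null.

    Joins the two series on individual id, computes the observed OLS
    slope, permutes the sMLH values ``n_perm`` times and reports the
    two-sided p-value (1 + #{|null| >= |obs|}) / (n_perm + 1).
    """
    joined = pd.concat([nec_int.rename("y"), smlh.rename("x")],
                       axis=1, join="inner").dropna()
    if len(joined) < 10:
        raise ValueError("need >= 10 individuals with both nec-int and sMLH")
    x = joined["x"].to_numpy(float)
    y = joined["y"].to_numpy(float)
    if x.std() == 0:
        raise ValueError("sMLH has zero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    var_x = float(xc @ xc)
    obs = float(xc @ yc) / var_x

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    xp = x.copy()
    for b in range(n_perm):
        rng.shuffle(xp)
        xpc = xp - xp.mean()
        null[b] = float(xpc @ yc) / float(xpc @ xpc)
    p = (1 + int(np.sum(np.abs(null) >= abs(obs)))) / (n_perm + 1)
    return HeterosisResult(obs, null, float(p), n_perm, len(joined))
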