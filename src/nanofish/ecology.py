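"""Community statistics: alpha diversity, Jaccard/PCoA/PERMANOVA,
beta-dispersion, accumulation curves, nonparametric tests, diel ratios and
the eDNA-vs-visual method comparison.

PERMANOVA uses distance-based partitioning with sequential (order-of-entry)
sums of squares for main effects and interaction, pseudo-F per term, and
free permutation of sample labels; permutation p-values use the add-one
convention (1 + exceedances) / (1 + permutations) and so are never zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- alpha

def alpha_diversity(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Shannon (natural log), Simpson (1 - sum p^2),
    and bias-corrected Chao1 with its singleton/doubleton inputs."""
    counts = table.counts if isinstance(table, CountTable) else table
    rows = []
    for s in counts.columns:
        col = counts[s].to_numpy(dtype=float)
        col = col[col > 0]
        if col.size == 0:
            raise ValueError(f"sample {s!r} has no reads")
        p = col / col.sum()
        f1 = int((col == 1).sum())
        f2 = int((col == 2).sum())
        rows.append(
            {
                "sample_id": s,
                "richness": int(col.size),
                "shannon": float(-(p * np.log(p)).sum()),
                "simpson": float(1.0 - (p**2).sum()),
                "chao1": float(col.size + f1 * (f1 - 1) / (2 * (f2 + 1))),
                "singletons": f1,
                "doubletons": f2,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ------------------------------------------------------------- distances

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])


def jaccard_matrix(table: CountTable | pd.DataFrame) -> DistanceMatrix:
    """Jaccard distances 1 - |A∩B| / |A∪B| on presence/absence profiles."""
    counts = table.counts if isinstance(table, CountTable) else table
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    presence = (counts.to_numpy() > 0).astype(int)
    labels = list(counts.columns)
    n = len(labels)
    d = np.zeros((n, n))
    empties = [labels[j] for j in range(n) if presence[:, j].sum() == 0]
    if empties:
        logger.warning("samples with no taxa: %s", empties)
    for i in range(n):
        for j in range(i + 1, n):
            inter = int(np.minimum(presence[:, i], presence[:, j]).sum())
            union = int(np.maximum(presence[:, i], presence[:, j]).sum())
            d[i, j] = d[j, i] = 1.0 - inter / union if union else 0.0
    return DistanceMatrix(labels, d)


# ----------------------------------------------------------------- PCoA

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    negative_inertia_fraction: float = 0.0


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates: eigendecomposition of the Gower-centered
    squared distance matrix; only positive-eigenvalue axes are returned."""
    g = _gower_center(d.values**2)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-8 * abs(eigvals[0])) if eigvals.size else 0.0
    positive = eigvals > tol
    neg_sum = float(-eigvals[eigvals < -tol].sum())
    total_abs = float(np.abs(eigvals).sum()) or 1.0
    neg_frac = neg_sum / total_abs
    if neg_frac > 0:
        logger.warning("dropping negative-eigenvalue axes (%.2f%% of inertia)",
                       100 * neg_frac)
    vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(vals)
    # deterministic axis signs: largest-magnitude loading positive
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    frame = pd.DataFrame(
        coords,
        index=d.labels,
        columns=[f"PCo{k + 1}" for k in range(coords.shape[1])],
    )
    return OrdinationResult(frame, vals, neg_frac)


# ------------------------------------------------------------- PERMANOVA

@dataclass
class PermanovaResult:
    table: pd.DataFrame  # df, sum_sq, r2, pseudo_f, p_value per term
    n_permutations: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _parse_formula(formula: str) -> list[str]:
    formula = formula.replace(" ", "")
    if "*" in formula:
        a, b = formula.split("*")
        return [a, b, f"{a}:{b}"]
    return formula.split("+")


def _dummy(values: pd.Series) -> np.ndarray:
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {values.name!r} is constant across samples")
    return np.column_stack([(values == lvl).to_numpy(float) for lvl in levels[1:]])


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(
    d: DistanceMatrix,
    factors: pd.DataFrame,
    formula: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA with sequential term attribution.

    ``factors`` is indexed by sample id; ``formula`` is e.g.
    ``"habitat * season"`` (two mains plus interaction) or ``"a + b"``.
    p-values come from free row permutations of the distance matrix.
    """
    factors = factors.loc[d.labels]
    terms = _parse_formula(formula)
    n = len(d.labels)
    g = _gower_center(d.values**2)
    ss_total = float(np.trace(g))

    design_blocks: list[np.ndarray] = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            da, db = _dummy(factors[a]), _dummy(factors[b])
            block = np.concatenate(
                [da[:, [i]] * db for i in range(da.shape[1])], axis=1
            )
        else:
            block = _dummy(factors[term])
        design_blocks.append(block)

    intercept = np.ones((n, 1))
    hats = []
    x = intercept
    h_prev = _hat(x)
    dfs = []
    for block in design_blocks:
        x = np.concatenate([x, block], axis=1)
        h = _hat(x)
        hats.append((h_prev, h))
        dfs.append(int(round(np.trace(h) - np.trace(h_prev))))
        h_prev = h
    h_full = h_prev
    resid_proj = np.eye(n) - h_full
    df_resid = int(round(np.trace(resid_proj)))
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    # per-term difference projections, flattened for fast traces
    term_mats = np.stack([(h - h0) for h0, h in hats])  # (T, n, n)
    tiny = 1e-12 * max(ss_total, 1.0)  # clip floating noise in traces

    def _clip(x):
        return np.where(np.abs(x) < tiny, 0.0, x)

    ss_terms = _clip(np.einsum("tij,ji->t", term_mats, g))
    ss_resid = float(_clip(np.einsum("ij,ji->", resid_proj, g)))
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_terms / np.array(dfs)) / (ss_resid / df_resid)
    f_obs = np.nan_to_num(f_obs, nan=0.0, posinf=np.inf)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    if n_perm > 0:
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        g_perm = g[perms[:, :, None], perms[:, None, :]]  # (B, n, n)
        ss_t = _clip(np.einsum("tij,bji->bt", term_mats, g_perm))
        ss_r = _clip(np.einsum("ij,bji->b", resid_proj, g_perm))
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ss_t / np.array(dfs)) / (ss_r / df_resid)[:, None]
        f_perm = np.nan_to_num(f_perm, nan=0.0, posinf=np.inf)
        exceed = (f_perm >= f_obs[None, :] - 1e-12).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": dfs[i],
                "sum_sq": float(ss_terms[i]),
                "r2": float(ss_terms[i] / ss_total),
                "pseudo_f": float(f_obs[i]),
                "p_value": float(p[i]),
            }
        )
    rows.append(
        {
            "term": "residual",
            "df": df_resid,
            "sum_sq": ss_resid,
            "r2": ss_resid / ss_total,
            "pseudo_f": np.nan,
            "p_value": np.nan,
        }
    )
    frame = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(frame, n_perm)


# -------------------------------------------------------- beta dispersion

@dataclass
class BetaDispersionResult:
    distances: pd.Series  # per-sample distance to its group centroid
    f_statistic: float
    p_value: float
    group_means: pd.Series


def beta_dispersion(
    d: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> BetaDispersionResult:
    """Homogeneity of multivariate dispersion: distance of each sample to
    its group centroid in PCoA space, with a permutation F-test."""
    groups = groups.loc[d.labels]
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")
    coords = pcoa(d).coordinates.to_numpy()

    def sample_dists(lab: np.ndarray) -> np.ndarray:
        out = np.empty(len(lab))
        for g in np.unique(lab):
            mask = lab == g
            if mask.sum() == 1:
                out[mask] = 0.0
                logger.warning("group %r has a single sample; zero dispersion", g)
                continue
            centroid = coords[mask].mean(axis=0)
            out[mask] = np.linalg.norm(coords[mask] - centroid, axis=1)
        return out

    def f_stat(dist: np.ndarray, lab: np.ndarray) -> float:
        grand = dist.mean()
        levels = np.unique(lab)
        ss_between = sum(
            (lab == g).sum() * (dist[lab == g].mean() - grand) ** 2 for g in levels
        )
        ss_within = sum(
            ((dist[lab == g] - dist[lab == g].mean()) ** 2).sum() for g in levels
        )
        df1, df2 = len(levels) - 1, len(dist) - len(levels)
        if ss_within <= 1e-300:
            return 0.0 if ss_between <= 1e-300 else math.inf
        return (ss_between / df1) / (ss_within / df2)

    lab = groups.to_numpy()
    dist = sample_dists(lab)
    f_obs = f_stat(dist, lab)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_p = f_stat(dist[rng.permutation(len(dist))], lab)
        if f_p >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    series = pd.Series(dist, index=d.labels, name="dist_to_centroid")
    means = series.groupby(groups).mean()
    return BetaDispersionResult(series, float(f_obs), float(p), means)


# ------------------------------------------------------- accumulation

def accumulation_curve(
    table: CountTable | pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean ± SD cumulative richness for k = 1..n samples.

    Exact over all sample subsets when n <= 8 (the first k samples of a
    random ordering are a uniform k-subset), Monte-Carlo otherwise.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    n = counts.shape[1]
    if n < 2:
        raise ValueError("need at least two samples")
    presence = [frozenset(counts.index[counts[s] > 0]) for s in counts.columns]
    rows = []
    if n <= 8:
        for k in range(1, n + 1):
            richness = [
                len(frozenset().union(*combo))
                for combo in itertools.combinations(presence, k)
            ]
            rows.append((k, float(np.mean(richness)), float(np.std(richness))))
    else:
        rng = np.random.default_rng(seed)
        acc = np.zeros((n_perm, n))
        for b in range(n_perm):
            seen: set = set()
            for k, idx in enumerate(rng.permutation(n)):
                seen |= presence[idx]
                acc[b, k] = len(seen)
        for k in range(n):
            rows.append((k + 1, float(acc[:, k].mean()), float(acc[:, k].std())))
    return pd.DataFrame(rows, columns=["n_samples", "mean_richness", "sd_richness"])


@dataclass
class AccumulationFit:
    a: float
    b: float
    threshold_n: int


def fit_log_accumulation(curve: pd.DataFrame) -> AccumulationFit:
    """Least-squares fit of S(n) = a + b ln(n) and the effort threshold.

    ``threshold_n`` is the smallest n >= 1 at which adding one more sample
    is expected to contribute less than one species: b·ln((n+1)/n) < 1.
    """
    if len(curve) < 3:
        raise ValueError("need at least three curve points")
    n = curve["n_samples"].to_numpy(dtype=float)
    s = curve["mean_richness"].to_numpy(dtype=float)
    x = np.column_stack([np.ones_like(n), np.log(n)])
    (a, b), *_ = np.linalg.lstsq(x, s, rcond=None)
    # gain at n=1 is b ln 2, so any slope under 1/ln 2 saturates immediately
    if b <= 1.0 / math.log(2):
        return AccumulationFit(float(a), float(b), 1)
    # b ln(1 + 1/n) < 1  <=>  n > 1 / (e^{1/b} - 1)
    threshold = max(1, math.floor(1.0 / (math.exp(1.0 / b) - 1.0)) + 1)
    while threshold > 1 and b * math.log((threshold) / (threshold - 1)) < 1:
        threshold -= 1
    return AccumulationFit(float(a), float(b), int(threshold))


# ------------------------------------------------------------ rank tests

def mann_whitney(
    x: list[float] | np.ndarray,
    y: list[float] | np.ndarray,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann–Whitney U with midrank ties; exact enumeration when both
    groups have at most 8 observations (and no ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    dunn: pd.DataFrame  # group_a, group_b, z, p_raw, p_adjusted


def kruskal_dunn(groups: dict[str, list[float]]) -> KruskalDunnResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn pairwise z-tests under
    Holm adjustment."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than two observations")
    names = list(groups)
    values = [np.asarray(groups[g], float) for g in names]
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        h, p_global = 0.0, 1.0
    else:
        h, p_global = stats.kruskal(*values)

    all_ranks = stats.rankdata(pooled)
    sizes = [len(v) for v in values]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        all_ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(names))
    ]
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    pvals = []
    for i, j in itertools.combinations(range(len(names)), 2):
        se = math.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": names[i], "group_b": names[j], "z": z, "p_raw": p_raw})
        pvals.append(p_raw)
    if rows:
        adjusted = multipletests(pvals, method="holm")[1]
        for row, adj in zip(rows, adjusted):
            row["p_adjusted"] = float(adj)
    dunn = pd.DataFrame(rows)
    return KruskalDunnResult(float(h), float(p_global), dunn)


# ------------------------------------------------------------ diel ratios

def diel_ratios(
    table: CountTable, traits: dict[str, str]
) -> pd.DataFrame:
    """Per-sample nocturnal read and species ratios.

    Denominators include only species with known activity ("diurnal",
    "nocturnal" or "both"); species labelled "both" never count as
    nocturnal. Samples with no activity-known species are flagged undefined.
    """
    ann = table.row_annotations
    rows = []
    labels = [
        str(ann.at[r, "species"]) if "species" in ann.columns else str(r)
        for r in table.row_ids
    ]
    activity = [traits.get(lbl, "unknown") for lbl in labels]
    known = np.array([a in ("diurnal", "nocturnal", "both") for a in activity])
    nocturnal = np.array([a == "nocturnal" for a in activity])
    for s in table.col_ids:
        col = table.counts[s].to_numpy(dtype=float)
        present = col > 0
        known_reads = float(col[known].sum())
        known_present = int((known & present).sum())
        rec = table.samples[s]
        if known_reads == 0 or known_present == 0:
            rows.append(
                {
                    "sample_id": s,
                    "clock_time": rec.clock_time,
                    "nocturnal_read_ratio": np.nan,
                    "nocturnal_species_ratio": np.nan,
                    "defined": False,
                }
            )
            continue
        rows.append(
            {
                "sample_id": s,
                "clock_time": rec.clock_time,
                "nocturnal_read_ratio": float(col[nocturnal].sum()) / known_reads,
                "nocturnal_species_ratio": int((nocturnal & present).sum())
                / known_present,
                "defined": True,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ------------------------------------------------- method comparison

@dataclass
class MethodComparison:
    edna_only: list[str]
    visual_only: list[str]
    shared: list[str]
    mean_abundance: dict[str, float]  # per class, mean over taxa of mean eDNA %


def method_comparison(
    edna: pd.DataFrame,
    visual: dict[str, float],
    composite_match: bool = False,
) -> MethodComparison:
    """Partition taxa into eDNA-only / visual-only / shared and report the
    per-class mean relative read abundance.

    ``edna`` holds per-sample relative abundances with NaN marking
    non-detection; a taxon's abundance is averaged over all eDNA columns
    with absences as zero, then averaged over the taxa of each class.
    With ``composite_match`` a visual species also matches an eDNA composite
    label containing it (e.g. "Pomacentrus pavo" vs "Pomacentrus
    pavo-coelestis"); by default composite labels count as their own taxa.
    """
    detected = edna.notna().any(axis=1)
    edna_taxa = [t for t in edna.index if detected[t]]

    def matches(visual_sp: str, edna_label: str) -> bool:
        if visual_sp == edna_label:
            return True
        if not composite_match:
            return False
        genus, epithet = (visual_sp.split(" ", 1) + [""])[:2]
        e_genus, e_rest = (edna_label.split(" ", 1) + [""])[:2]
        return genus == e_genus and epithet in e_rest.split("-")

    shared, edna_only = [], []
    matched_visual: set[str] = set()
    for taxon in edna_taxa:
        hit = [sp for sp in visual if matches(sp, taxon)]
        if hit:
            shared.append(taxon)
            matched_visual.update(hit)
        else:
            edna_only.append(taxon)
    visual_only = [sp for sp in visual if sp not in matched_visual]

    mean_abund = edna.fillna(0.0).mean(axis=1)
    per_class = {}
    for name, taxa in (("edna_only", edna_only), ("shared", shared)):
        per_class[name] = float(mean_abund.loc[taxa].mean()) if taxa else 0.0
    per_class["visual_only"] = 0.0
    return MethodComparison(edna_only, visual_only, shared, per_class)
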