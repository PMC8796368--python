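"""Cohort-level analysis of the fitted dependency-parameter table.

Consumes the (sample x chromosome) table of posterior means produced by
the per-track fits and answers the cohort questions: how consistent are
the parameters across chromosomes within individuals (ICC with
chromosomes as replicates); do paired individuals (true co-twins, random
pairs, batch-matched random pairs) differ in their dependency parameters
(squared-difference D statistics, one-sided Mann-Whitney tests, combined
across chromosomes with an extended Fisher's method for correlated
tests); how does the relative range vary across chromosomes and with
chromosome annotation (Spearman correlations); and how the parameters
shift between age groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .methylation_io import ProbeManifest, SampleSheet

logger = logging.getLogger("methdep")

__all__ = [
    "PairingScheme",
    "CombinedTestResult",
    "select_one_per_family",
    "icc_oneway",
    "build_pairing",
    "select_representative_pairing",
    "pair_squared_diffs",
    "mann_whitney_one_sided",
    "combine_correlated_pvalues",
    "relative_range",
    "spearman_with_ci",
    "island_proportions",
    "age_group_contrast",
    "table1_analogue",
]

PAIRING_SCHEMES = ("true_twins", "random", "matched_plate", "matched_plate_chip")


@dataclass
class PairingScheme:
    """One concrete pairing of samples under a scheme."""

    label: str
    pairs: list
    seed: int | None = None
    repeat_index: int | None = None
    unpaired: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"sample {a!r} paired with itself")
            if a in seen or b in seen:
                raise ValueError("pairs are not disjoint")
            seen.update((a, b))


@dataclass
class CombinedTestResult:
    """Extended-Fisher combination of correlated per-chromosome tests."""

    p_by_chrom: pd.Series
    correlation: pd.DataFrame
    statistic_x: float
    scale_c: float
    dof_f: float
    p_combined: float


# ---------------------------------------------------------------------------
# ICC


def select_one_per_family(sheet: SampleSheet, seed: int) -> list[str]:
    """One randomly chosen sample id per family (selection seed recorded
    by the caller)."""
    rng = np.random.default_rng(seed)
    chosen = []
    for fam, grp in sheet.table.groupby("family_id", sort=True):
        ids = sorted(grp["sample_id"].tolist())
        chosen.append(ids[rng.integers(len(ids))])
    return chosen


def icc_oneway(
    table: pd.DataFrame,
    value_col: str,
    subject_col: str = "sample_id",
    confidence: float = 0.95,
) -> dict:
    """One-way random-effects ICC(1,1) with chromosomes as replicates.

    ``(MSB - MSW) / (MSB + (k-1) * MSW)`` with the standard unbalanced
    one-way correction ``k0 = (N - sum(n_i^2)/N) / (a-1)`` for unequal
    replicate counts; the confidence interval comes from the F
    distribution.
    """
    df = table[[subject_col, value_col]].dropna()
    counts = df.groupby(subject_col)[value_col].count()
    if len(counts) < 2:
        raise ValueError("need at least 2 subjects for an ICC")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"subjects with fewer than 2 replicates: {bad[:5]}")
    n_total = int(counts.sum())
    a = len(counts)
    grand = df[value_col].mean()
    group_means = df.groupby(subject_col)[value_col].mean()
    ssb = float((counts * (group_means - grand) ** 2).sum())
    sse_by = df.groupby(subject_col)[value_col].apply(lambda v: ((v - v.mean()) ** 2).sum())
    ssw = float(sse_by.sum())
    msb = ssb / (a - 1)
    msw = ssw / (n_total - a)
    k0 = (n_total - float((counts**2).sum()) / n_total) / (a - 1)
    if msw == 0.0:
        if msb == 0.0:
            raise ValueError("all values identical; ICC undefined")
        return {
            "icc": 1.0, "ci_low": 1.0, "ci_high": 1.0,
            "n_subjects": a, "k": k0, "msb": msb, "msw": msw,
        }
    icc = (msb - msw) / (msb + (k0 - 1.0) * msw)
    alpha = 1.0 - confidence
    df1, df2 = a - 1, n_total - a
    f_obs = msb / msw
    f_l = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (f_l - 1.0) / (f_l + k0 - 1.0)
    ci_high = (f_u - 1.0) / (f_u + k0 - 1.0)
    return {
        "icc": icc,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "n_subjects": a,
        "k": k0,
        "msb": msb,
        "msw": msw,
    }


# ---------------------------------------------------------------------------
# pairings and D statistics


def _pair_within_stratum(ids: list, co_twins: set, rng) -> tuple[list, list]:
    """Random disjoint pairs within one stratum, avoiding true co-twin
    pairs; one sample left unpaired on odd sizes."""
    ids = sorted(ids)
    rng.shuffle(ids)
    unpaired = []
    if len(ids) % 2 == 1:
        unpaired.append(ids.pop())
    pairs = [(ids[2 * i], ids[2 * i + 1]) for i in range(len(ids) // 2)]
    dropped = []
    for i, (a, b) in enumerate(pairs):
        if frozenset((a, b)) not in co_twins:
            continue
        fixed = False
        for j in range(len(pairs)):
            if j == i or pairs[j] is None:
                continue
            c, d = pairs[j]
            if (
                frozenset((a, d)) not in co_twins
                and frozenset((c, b)) not in co_twins
            ):
                pairs[i] = (a, d)
                pairs[j] = (c, b)
                fixed = True
                break
        if not fixed:
            dropped.append(i)
    for i in sorted(dropped, reverse=True):
        unpaired.extend(pairs[i])
        pairs.pop(i)
    return pairs, unpaired


def build_pairing(
    sheet: SampleSheet,
    scheme: str,
    seed: int = 0,
    n_repeats: int = 100,
    sample_ids: list | None = None,
) -> list[PairingScheme]:
    """Candidate pairings under one scheme.

    ``true_twins`` returns a single deterministic pairing (each co-twin
    pair once).  The random schemes return ``n_repeats`` independent
    pairings (seeded); pair members share the matching attribute(s) and
    are never true co-twins.  Use
    :func:`select_representative_pairing` to pick the representative
    repeat by the rank of its median D.
    """
    if scheme not in PAIRING_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {PAIRING_SCHEMES}")
    t = sheet.table
    if sample_ids is not None:
        t = t[t["sample_id"].isin(sample_ids)]
    if scheme == "true_twins":
        pairs = []
        for pid, grp in t.groupby("pair_id", sort=True):
            ids = sorted(grp["sample_id"].tolist())
            if len(ids) == 2:
                pairs.append((ids[0], ids[1]))
        return [PairingScheme(label=scheme, pairs=pairs, seed=None, repeat_index=None)]

    co_twins = sheet.co_twin_pairs()
    if scheme == "random":
        strata_cols: list[str] = []
    elif scheme == "matched_plate":
        strata_cols = ["plate"]
    else:
        strata_cols = ["plate", "beadchip"]
    out = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([int(seed), rep])
        pairs: list = []
        unpaired: list = []
        if strata_cols:
            for _, grp in t.groupby(strata_cols, sort=True):
                p, u = _pair_within_stratum(grp["sample_id"].tolist(), co_twins, rng)
                pairs.extend(p)
                unpaired.extend(u)
        else:
            pairs, unpaired = _pair_within_stratum(
                t["sample_id"].tolist(), co_twins, rng
            )
        if len(pairs) < 1:
            raise ValueError(f"scheme {scheme!r}: fewer than 2 usable samples")
        if unpaired:
            logger.debug("scheme %s repeat %d: %d unpaired", scheme, rep, len(unpaired))
        out.append(
            PairingScheme(
                label=scheme, pairs=pairs, seed=int(seed), repeat_index=rep,
                unpaired=unpaired,
            )
        )
    return out


def pair_squared_diffs(
    table: pd.DataFrame,
    pairing: PairingScheme,
    parameters: tuple[str, ...] = ("post_mean_logtau", "post_mean_logkappa"),
) -> pd.DataFrame:
    """Per pair, per chromosome squared differences of the parameters.

    Returns a long table with columns sample_a, sample_b, chrom and
    ``d_<parameter>``; chromosomes missing for either member are skipped,
    pairs with no common chromosome are dropped with a warning.
    """
    wide = {
        p: table.pivot(index="sample_id", columns="chrom", values=p)
        for p in parameters
    }
    any_wide = next(iter(wide.values()))
    known = set(any_wide.index)
    kept = [(a, b) for a, b in pairing.pairs if a in known and b in known]
    n_dropped = len(pairing.pairs) - len(kept)
    if not kept:
        return pd.DataFrame(
            columns=["sample_a", "sample_b", "chrom"]
            + [f"d_{p}" for p in parameters]
        )
    a_ids = [a for a, _ in kept]
    b_ids = [b for _, b in kept]
    chroms = any_wide.columns.to_numpy()
    out = pd.DataFrame(
        {
            "sample_a": np.repeat(a_ids, chroms.size),
            "sample_b": np.repeat(b_ids, chroms.size),
            "chrom": np.tile(chroms, len(kept)),
        }
    )
    keep_mask = np.ones(len(out), dtype=bool)
    for p, w in wide.items():
        diff = w.loc[a_ids].to_numpy() - w.loc[b_ids].to_numpy()
        d = (diff**2).ravel()
        out[f"d_{p}"] = d
        keep_mask &= np.isfinite(d)
    out = out[keep_mask].reset_index(drop=True)
    n_dropped += len(kept) - out["sample_a"].nunique() if len(out) else 0
    if n_dropped:
        logger.warning(
            "pair_squared_diffs: dropped %d pairs (missing from the table or "
            "no shared chromosomes)",
            n_dropped,
        )
    return out


def select_representative_pairing(
    candidates: list[PairingScheme],
    table: pd.DataFrame,
    parameter: str = "post_mean_logtau",
) -> PairingScheme:
    """Representative repeat among random pairings.

    Each candidate's D distribution is summarized by its median; the
    candidate whose median has rank ceil(n/2) (1-based) among the
    candidates is returned.
    """
    if len(candidates) == 1:
        return candidates[0]
    medians = []
    for cand in candidates:
        d = pair_squared_diffs(table, cand, parameters=(parameter,))
        medians.append(float(d[f"d_{parameter}"].median()))
    order = np.argsort(np.asarray(medians), kind="stable")
    pick = order[int(math.ceil(len(candidates) / 2)) - 1]
    return candidates[int(pick)]


# ---------------------------------------------------------------------------
# tests


def mann_whitney_one_sided(group_greater, group_lesser) -> dict:
    """One-sided Mann-Whitney U test (alternative: first group larger).

    Exact enumeration when m + n <= 20 and there are no ties; otherwise
    the normal approximation with midranks and tie correction.
    """
    x = np.asarray(group_greater, dtype=float)
    y = np.asarray(group_lesser, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return {"U": float(x.size * y.size / 2.0), "p": 1.0}
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="greater", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def _kost_mcdermott_cov(rho: float) -> float:
    """Polynomial approximation of cov(-2 ln p_i, -2 ln p_j) as a function
    of the correlation of the underlying statistics."""
    return 3.263 * rho + 0.710 * rho**2 + 0.027 * rho**3


def combine_correlated_pvalues(
    p_by_chrom: pd.Series | dict,
    estimates: pd.DataFrame | np.ndarray,
    p_floor: float = 1e-300,
) -> CombinedTestResult:
    """Extended Fisher's method (Brown family) for correlated tests.

    ``X = -2 sum(ln p_j)`` is referred to a scaled chi-square ``c * chi2_f``
    whose first two moments match ``E[X] = 2k`` and ``Var(X) = 4k +
    2 sum_{i<j} cov_ij``, with the pairwise covariances from the
    Kost-McDermott polynomial in the between-chromosome correlation of
    the per-individual estimates.  With zero correlation this is exactly
    Fisher's method.
    """
    p = pd.Series(p_by_chrom).astype(float)
    if ((p <= 0) | (p > 1)).any():
        n_bad = int((p <= 0).sum())
        if ((p > 1).any()) or not n_bad:
            raise ValueError("p-values must lie in (0, 1]")
        logger.warning("flooring %d zero p-values at %.1e", n_bad, p_floor)
        p = p.clip(lower=p_floor)
    est = pd.DataFrame(estimates)
    if est.shape[1] != len(p):
        raise ValueError(
            f"estimates have {est.shape[1]} chromosome columns but "
            f"{len(p)} p-values were given"
        )
    k = len(p)
    corr = est.corr(method="pearson").to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-8:
        shrink = min(1.0, -eigmin / (1.0 - eigmin) + 1e-6)
        logger.warning(
            "correlation matrix not positive semidefinite (min eig %.2e); "
            "shrinking toward identity by %.3f",
            eigmin,
            shrink,
        )
        corr = (1.0 - shrink) * corr + shrink * np.eye(k)
    x_stat = float(-2.0 * np.log(p).sum())
    e_x = 2.0 * k
    cov_sum = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            cov_sum += _kost_mcdermott_cov(float(corr[i, j]))
    var_x = 4.0 * k + 2.0 * cov_sum
    var_x = max(var_x, 1e-12)
    c = var_x / (2.0 * e_x)
    f = 2.0 * e_x**2 / var_x
    p_comb = float(sps.chi2.sf(x_stat / c, f))
    corr_df = pd.DataFrame(corr, index=p.index, columns=p.index)
    return CombinedTestResult(
        p_by_chrom=p,
        correlation=corr_df,
        statistic_x=x_stat,
        scale_c=c,
        dof_f=f,
        p_combined=p_comb,
    )


# ---------------------------------------------------------------------------
# chromosome profiles


def relative_range(table: pd.DataFrame, value_col: str = "range_bp"):
    """Per-chromosome median of within-individual relative range.

    Each individual's range estimates are divided by that individual's
    median across chromosomes; the per-chromosome median of these relative
    values across individuals is reported (unclipped), alongside the full
    relative-value table.
    """
    df = table[["sample_id", "chrom", value_col]].dropna().copy()
    med = df.groupby("sample_id")[value_col].transform("median")
    bad = med <= 0
    if bad.any():
        excluded = df.loc[bad, "sample_id"].unique()
        logger.warning("relative_range: excluding %d individuals with zero median",
                       len(excluded))
        df, med = df[~bad], med[~bad]
    df["relative"] = df[value_col] / med
    per_chrom = df.groupby("chrom")["relative"].median()
    per_chrom.name = "median_relative_range"
    return per_chrom, df[["sample_id", "chrom", "relative"]]


def spearman_with_ci(x, y, confidence: float = 0.95) -> dict:
    """Spearman correlation with a Fisher-z confidence interval
    (sd 1/sqrt(n-3) applied to rho)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length inputs of size >= 4")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    z = math.atanh(max(min(rho, 1 - 1e-15), -1 + 1e-15))
    half = sps.norm.ppf(0.5 + confidence / 2.0) / math.sqrt(x.size - 3)
    return {
        "rho": float(rho),
        "ci_low": math.tanh(z - half),
        "ci_high": math.tanh(z + half),
        "p": float(p),
        "n": int(x.size),
    }


def island_proportions(manifest: ProbeManifest) -> pd.Series:
    """Per-chromosome proportion of island probes, relative to the median
    proportion across chromosomes."""
    t = manifest.table
    prop = t.groupby("chrom")["island"].mean()
    if (t.groupby("chrom").size() == 0).any():  # pragma: no cover - groupby drops
        pass
    med = prop.median()
    if med == 0:
        raise ValueError("median island proportion is zero")
    rel = prop / med
    rel.name = "relative_island_proportion"
    return rel


# ---------------------------------------------------------------------------
# group contrasts


def _per_chromosome_mw(
    table: pd.DataFrame,
    value_col: str,
    ids_greater: set,
    ids_lesser: set,
) -> pd.Series:
    ps = {}
    for chrom, grp in table.groupby("chrom"):
        g = grp.loc[grp["sample_id"].isin(ids_greater), value_col].dropna()
        l = grp.loc[grp["sample_id"].isin(ids_lesser), value_col].dropna()
        if g.empty or l.empty:
            raise ValueError(f"empty group on chromosome {chrom}")
        ps[chrom] = mann_whitney_one_sided(g, l)["p"]
    return pd.Series(ps).sort_index()


def age_group_contrast(
    table: pd.DataFrame,
    parameters: dict | None = None,
    age_threshold_young: float = 40.0,
    age_threshold_old: float = 50.0,
) -> dict:
    """Compare each parameter between the young (< threshold) and old
    (> threshold) individuals, per chromosome, combined across chromosomes.

    ``parameters`` maps column name -> alternative direction
    ("young_greater" or "old_greater"); the defaults test the shifts the
    model anticipates: lower log tau (more spatial variance) and higher
    variance-explained in the older group.
    """
    if parameters is None:
        parameters = {
            "post_mean_logtau": "young_greater",
            "post_mean_logkappa": "young_greater",
            "var_explained": "old_greater",
        }
    if "age" not in table.columns:
        raise ValueError("table must carry an 'age' column (join the sample sheet)")
    young = table[table["age"] < age_threshold_young]
    old = table[table["age"] > age_threshold_old]
    if young.empty or old.empty:
        raise ValueError("one of the age groups is empty")
    results = {}
    for col, direction in parameters.items():
        both = pd.concat([young, old])
        ids_y = set(young["sample_id"])
        ids_o = set(old["sample_id"])
        if direction == "young_greater":
            ids_g, ids_l = ids_y, ids_o
        elif direction == "old_greater":
            ids_g, ids_l = ids_o, ids_y
        else:
            raise ValueError(f"unknown direction {direction!r}")
        p_chrom = _per_chromosome_mw(both, col, ids_g, ids_l)
        est = both.pivot_table(index="sample_id", columns="chrom", values=col)
        combined = combine_correlated_pvalues(p_chrom, est)
        summaries = both.assign(
            group=np.where(both["sample_id"].isin(ids_y), "young", "old")
        ).groupby(["chrom", "group"])[col].median().unstack()
        results[col] = {
            "direction": direction,
            "combined": combined,
            "group_medians": summaries,
            "n_young": len(ids_y),
            "n_old": len(ids_o),
        }
    return results


def _combined_from_pairdiffs(
    d_greater: pd.DataFrame, d_lesser: pd.DataFrame, param: str
) -> CombinedTestResult:
    col = f"d_{param}"
    chroms = sorted(set(d_greater["chrom"]) & set(d_lesser["chrom"]))
    ps = {}
    for chrom in chroms:
        g = d_greater.loc[d_greater["chrom"] == chrom, col]
        l = d_lesser.loc[d_lesser["chrom"] == chrom, col]
        ps[chrom] = mann_whitney_one_sided(g, l)["p"]
    pooled = pd.concat([d_greater, d_lesser], ignore_index=True)
    pooled["pair"] = pooled["sample_a"] + "|" + pooled["sample_b"]
    est = pooled.pivot_table(index="pair", columns="chrom", values=col)
    est = est[chroms]
    return combine_correlated_pvalues(pd.Series(ps).sort_index(), est)


def table1_analogue(
    table: pd.DataFrame,
    sheet: SampleSheet,
    seed: int = 0,
    n_repeats: int = 100,
    parameters: tuple[str, ...] = ("post_mean_logtau", "post_mean_logkappa"),
) -> tuple[pd.DataFrame, dict]:
    """The eight pairing contrasts of the cohort analysis, one row each.

    Builds the four pairing schemes (true twins; random; random matched on
    plate; random matched on plate and BeadChip, representatives of
    ``n_repeats`` random draws chosen by median D), computes squared
    log-parameter differences per pair and chromosome, and tests each
    one-sided contrast with Mann-Whitney per chromosome combined across
    chromosomes.  Returns the result table and the pairings used (for
    audit).
    """
    meta = sheet.table.set_index("sample_id")
    schemes: dict[str, PairingScheme] = {}
    for scheme in PAIRING_SCHEMES:
        cands = build_pairing(sheet, scheme, seed=seed, n_repeats=n_repeats)
        schemes[scheme] = select_representative_pairing(cands, table, parameters[0])
    dsets = {name: pair_squared_diffs(table, p, parameters)
             for name, p in schemes.items()}

    tw = dsets["true_twins"]

    def pair_attr(df: pd.DataFrame, col: str):
        return (
            meta.loc[df["sample_a"], col].to_numpy()
            == meta.loc[df["sample_b"], col].to_numpy()
        )

    zyg = meta.loc[tw["sample_a"], "zygosity"].to_numpy()
    same_chip = pair_attr(tw, "beadchip")
    same_sex = pair_attr(tw, "sex")
    mz, dz = zyg == "MZ", zyg == "DZ"

    contrasts = [
        ("random_gt_matched_plate", dsets["random"], dsets["matched_plate"]),
        (
            "matched_plate_gt_matched_plate_chip",
            dsets["matched_plate"],
            dsets["matched_plate_chip"],
        ),
        ("matched_plate_gt_true_twins", dsets["matched_plate"], tw),
        ("matched_plate_chip_gt_true_twins", dsets["matched_plate_chip"], tw),
        ("mz_diff_chip_gt_mz_same_chip", tw[mz & ~same_chip], tw[mz & same_chip]),
        ("dz_diff_chip_gt_dz_same_chip", tw[dz & ~same_chip], tw[dz & same_chip]),
        ("dz_gt_mz", tw[dz], tw[mz]),
        ("opp_sex_dz_gt_same_sex_dz", tw[dz & ~same_sex], tw[dz & same_sex]),
    ]
    rows = []
    for name, d_g, d_l in contrasts:
        rec = {
            "contrast": name,
            "n_pairs_greater": d_g["sample_a"].nunique() if len(d_g) else 0,
            "n_pairs_lesser": d_l["sample_a"].nunique() if len(d_l) else 0,
        }
        for param in parameters:
            if len(d_g) == 0 or len(d_l) == 0:
                rec[f"p_combined_{param}"] = math.nan
                continue
            res = _combined_from_pairdiffs(d_g, d_l, param)
            rec[f"p_combined_{param}"] = res.p_combined
        rows.append(rec)
    return pd.DataFrame(rows), schemes
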