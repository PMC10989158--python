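"""Treatment comparisons and index <-> food-web association analysis.

Two layers validate the enzyme-profile indices against the reference
micro-food-web features: per-index two-sample T tests between treatments
(Welch by default, optionally pooled-variance and/or stratified by
season), and a Pearson correlation matrix over declared
(enzyme index, food-web feature) pairs with pairwise deletion of missing
values and a per-cell alpha = 0.05 significance flag (an optional
Benjamini-Hochberg correction is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ValidationError

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Welch/Student T-test result for one index between two treatments."""

    index: str
    season: str  # "pooled" or a season label
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float
    percent_change: float

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def _welch(a: np.ndarray, b: np.ndarray, pooled: bool) -> tuple[float, float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        return np.nan, np.nan, np.nan
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math_sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = math_sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (a.mean() - b.mean()) / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return t, df, p


def math_sqrt(x: float) -> float:
    return float(np.sqrt(x))


def compare_groups(
    values: pd.Series,
    metadata: pd.DataFrame,
    stratify_by_season: bool = False,
    baseline: str | None = None,
    pooled_variance: bool = False,
) -> list[GroupComparison]:
    """T test of an index between the two treatment levels.

    ``baseline`` names the reference level (default: first level in sorted
    order); percent change is 100*(mean_other - mean_baseline)/mean_baseline.
    With ``stratify_by_season`` one comparison per season is returned in
    addition to the pooled one.
    """
    md = metadata.loc[values.index.intersection(metadata.index)]
    vals = values.loc[md.index]
    levels = sorted(md["treatment"].unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 treatment levels, got {levels}")
    if baseline is None:
        baseline = levels[0]
    elif baseline not in levels:
        raise ValidationError(f"baseline {baseline!r} not a treatment level")
    other = next(l for l in levels if l != baseline)

    strata = [("pooled", vals, md)]
    if stratify_by_season:
        for season in sorted(md["season"].unique()):
            mask = md["season"] == season
            strata.append((str(season), vals[mask], md[mask]))

    out = []
    for season, v, m in strata:
        a = v[m["treatment"] == baseline].dropna().to_numpy(dtype=float)
        b = v[m["treatment"] == other].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(
                f"treatment level with <2 samples in stratum {season!r}"
            )
        t, df, p = _welch(a, b, pooled_variance)
        if np.isnan(p):
            logger.warning("%s (%s): zero variance in both groups, p missing",
                           values.name, season)
        pct = 100.0 * (b.mean() - a.mean()) / a.mean() if a.mean() != 0 else np.nan
        out.append(GroupComparison(
            index=str(values.name), season=season,
            group_a=baseline, group_b=other,
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
            t=float(t), df=float(df), p=float(p), percent_change=float(pct),
        ))
    return out


def compare_all(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    stratify_by_season: bool = True,
    baseline: str | None = None,
) -> pd.DataFrame:
    """T tests for every column of an index table, long format."""
    rows = []
    for col in table.columns:
        try:
            comps = compare_groups(table[col], metadata, stratify_by_season,
                                   baseline)
        except ValidationError:
            continue
        rows.extend(c.to_series() for c in comps)
    return pd.DataFrame(rows).reset_index(drop=True)


def _pearson_cell(x: pd.Series, y: pd.Series) -> tuple[float, float, int]:
    ok = x.notna() & y.notna()
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xv, yv = x[ok].to_numpy(dtype=float), y[ok].to_numpy(dtype=float)
    if xv.std() == 0 or yv.std() == 0:
        logger.warning("constant variable in Pearson cell; result missing")
        return np.nan, np.nan, n
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p), n


def pearson_matrix(
    left: pd.DataFrame,
    right: pd.DataFrame,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Pearson r, p and n for every (left column, right column) pair.

    Samples are matched by sample_id; missing values are removed pairwise.
    Long format: index, feature, r, p, n, significant.
    """
    shared = left.index.intersection(right.index)
    if len(shared) == 0:
        raise ValidationError("no shared samples between index tables")
    l, r_ = left.loc[shared], right.loc[shared]
    rows = []
    for a in l.columns:
        for b in r_.columns:
            r, p, n = _pearson_cell(l[a], r_[b])
            rows.append({"index": a, "feature": b, "r": r, "p": p, "n": n})
    df = pd.DataFrame(rows)
    if fdr:
        df["p_adj"] = _benjamini_hochberg(df["p"].to_numpy())
        df["significant"] = df["p_adj"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(p)
    out = np.full_like(p, np.nan, dtype=float)
    ps = p[ok]
    m = len(ps)
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


#: (enzyme index, food-web feature) pairs evaluated by default, mirroring
#: the hypothesized index <-> feature correspondences: stoichiometry vs
#: substrate C:N, decomposability vs oxidizable-C share, channel index vs
#: microbial/faunal channel indices, composition vs composition, Shannon
#: sub-profiles vs community Shannon, gross activity vs quantity,
#: abundance and diversity.
DEFAULT_PAIRING: list[tuple[str, str]] = (
    [("BG_NAG", f) for f in ("TOC_TN", "DOC_DN")]
    + [("BG_PHOX", f) for f in ("DOC_TOC_pct", "CKMnO4_TOC_pct")]
    + [("NAG_LAP", f) for f in ("FB", "NCR", "NCI", "PCI")]
    + [("pco1_composition", f) for f in
       ("bacteria_pco1", "fungi_pco1", "protozoa_pco1", "nematode_pco1",
        "avg_pco1")]
    + [(s, f)
       for s in ("shannon_whole", "shannon_Cdeg", "shannon_hydrolase",
                 "shannon_Chydrolase")
       for f in ("bacteria_shannon", "fungi_shannon", "protozoa_shannon",
                 "nematode_shannon", "avg_z_shannon")]
    + [("gross_activity", f) for f in
       ("TOC", "DOC", "CKMnO4", "TN", "DN",
        "gene_copies_bacteria", "gene_copies_fungi", "abundance_protozoa",
        "abundance_nematode", "avg_z_abundance",
        "bacteria_shannon", "fungi_shannon", "protozoa_shannon",
        "nematode_shannon", "avg_z_shannon")]
)


def figure_panel(
    enzyme_idx: pd.DataFrame,
    foodweb_idx: pd.DataFrame,
    pairing: list[tuple[str, str]] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Association matrix restricted to a declared pairing.

    Only listed (index, feature) cells are evaluated; everything else is
    left blank (absent rows / NaN cells in the pivot). Duplicated pairs
    are deduplicated with a warning; unknown names are an error.
    """
    if pairing is None:
        pairing = [(a, b) for a, b in DEFAULT_PAIRING
                   if a in enzyme_idx.columns and b in foodweb_idx.columns]
    seen = set()
    unique = []
    for pair in pairing:
        if pair in seen:
            logger.warning("duplicate pair %r in pairing spec; deduplicated", pair)
            continue
        seen.add(pair)
        unique.append(pair)
    for a, b in unique:
        if a not in enzyme_idx.columns:
            raise ValidationError(f"pairing references unknown index {a!r}")
        if b not in foodweb_idx.columns:
            raise ValidationError(f"pairing references unknown feature {b!r}")
    shared = enzyme_idx.index.intersection(foodweb_idx.index)
    if len(shared) == 0 and unique:
        raise ValidationError("no shared samples between index tables")
    rows = []
    for a, b in unique:
        r, p, n = _pearson_cell(enzyme_idx.loc[shared, a],
                                foodweb_idx.loc[shared, b])
        rows.append({"index": a, "feature": b, "r": r, "p": p, "n": n,
                     "significant": bool(p < alpha) if not np.isnan(p) else False})
    return pd.DataFrame(rows, columns=["index", "feature", "r", "p", "n",
                                       "significant"])


def pivot_r(panel: pd.DataFrame) -> pd.DataFrame:
    """Wide matrix of r values; unevaluated cells are NaN (blank)."""
    if panel.empty:
        return pd.DataFrame()
    return panel.pivot(index="index", columns="feature", values="r")
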