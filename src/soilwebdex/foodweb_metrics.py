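"""Reference micro-food-web features the enzyme indices are validated against.

Covers rarefied alpha diversity (richness, Shannon, Pielou), substrate
stoichiometry/decomposability ratios, the decomposition channel indices
(F:B from gene copies; NCR and NCI from nematode trophic guilds; PCI from
protozoa feeding habits) and the z-score aggregation used to summarize the
whole four-group microbiota community.

Channel index formulas:

    NCR = B / (B + F)                      B, F: bacterivore, fungivore counts
    NCI = 100 * 0.8*Fu2 / (3.2*Ba1 + 0.8*Fu2)
                                           Ba1: bacterivorous cp-1 count
                                           Fu2: fungivorous cp-2 count
    PCI = relative abundance fungivorous / bacterivorous protozoa
    F:B = fungal / bacterial rRNA gene copies

Nematode analyses use only the free-living trophic groups (bacterivores,
fungivores, omnivore-predators); herbivores are excluded before
rarefaction. Natural logs throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_tables import (
    CommunityTable,
    FREE_LIVING_TROPHIC_GROUPS,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: default rarefaction depth for nematode communities (individuals)
NEMATODE_DEPTH = 100


def rarefy(ct: CommunityTable, depth: int | None = None, seed: int = 1) -> CommunityTable:
    """Subsample each sample without replacement to exactly ``depth`` counts.

    One multivariate-hypergeometric draw per sample, deterministic given
    ``seed``. ``depth`` defaults to the minimum sample total.
    """
    totals = ct.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    short = totals[totals < depth]
    if len(short):
        raise ValidationError(
            f"sample {short.index[0]!r} has {short.iloc[0]} counts < depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(ct.counts.shape, dtype=np.int64)
    for i, (_, row) in enumerate(ct.counts.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    counts = pd.DataFrame(out, index=ct.counts.index, columns=ct.counts.columns)
    return CommunityTable(group=ct.group, counts=counts, annotations=ct.annotations)


def free_living(ct: CommunityTable) -> CommunityTable:
    """Restrict a nematode table to free-living trophic groups."""
    if ct.group != "nematode":
        return ct
    if ct.annotations is None or "trophic_group" not in ct.annotations.columns:
        raise ValidationError("nematode table lacks trophic_group annotations")
    keep = ct.annotations.index[
        ct.annotations["trophic_group"].isin(FREE_LIVING_TROPHIC_GROUPS)
    ]
    return CommunityTable(
        group="nematode",
        counts=ct.counts[[t for t in ct.taxa if t in set(keep)]],
        annotations=ct.annotations.loc[keep],
    )


def alpha_diversity(ct: CommunityTable) -> pd.DataFrame:
    """Richness, Shannon H' (nats) and Pielou evenness per sample.

    Expects rarefied counts (the caller rarefies; a reminder is logged).
    Pielou = H'/ln(richness), missing when richness is 1.
    """
    totals = ct.sample_totals()
    if (totals == 0).any():
        raise ValidationError("empty sample in alpha_diversity")
    if totals.nunique() > 1:
        logger.info("alpha_diversity: sample totals differ; counts look unrarefied")
    x = ct.counts.to_numpy(dtype=float)
    richness = (x > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = x / x.sum(axis=1, keepdims=True)
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
        pielou = np.where(richness > 1, h / np.log(richness), np.nan)
    return pd.DataFrame(
        {"richness": richness, "shannon": h, "pielou": pielou},
        index=ct.counts.index,
    )


def fb_ratio(substrate: pd.DataFrame) -> pd.Series:
    """Fungal:bacterial gene-copy ratio per sample."""
    for col in ("gene_copies_fungi", "gene_copies_bacteria"):
        if col not in substrate.columns:
            raise ValidationError(f"substrate table missing column {col!r}")
    b = substrate["gene_copies_bacteria"]
    out = substrate["gene_copies_fungi"] / b.where(b > 0)
    if out.isna().any():
        logger.warning("F:B undefined for %d samples", int(out.isna().sum()))
    return out.rename("FB")


def _trophic_sum(ct: CommunityTable, mask: pd.Series) -> pd.Series:
    taxa = ct.annotations.index[mask]
    return ct.counts[[t for t in ct.taxa if t in set(taxa)]].sum(axis=1)


def ncr(ct: CommunityTable) -> pd.Series:
    """Nematode channel ratio B/(B+F); 1 = fully bacterial channel."""
    if ct.annotations is None or "trophic_group" not in ct.annotations.columns:
        raise ValidationError("NCR needs nematode trophic_group annotations")
    tg = ct.annotations["trophic_group"]
    if not tg.isin(["bacterivore", "fungivore"]).any():
        raise ValidationError("no bacterivore/fungivore nematodes annotated")
    b = _trophic_sum(ct, tg == "bacterivore")
    f = _trophic_sum(ct, tg == "fungivore")
    out = b / (b + f).where(b + f > 0)
    return out.rename("NCR")


def nci(ct: CommunityTable) -> pd.Series:
    """Nematode channel index, 0 (bacterial) to 100 (fungal).

    100 * 0.8*Fu2 / (3.2*Ba1 + 0.8*Fu2), with Ba1/Fu2 the bacterivorous
    cp-1 and fungivorous cp-2 abundances.
    """
    ann = ct.annotations
    if ann is None or "trophic_group" not in ann.columns or "cp_class" not in ann.columns:
        raise ValidationError("NCI needs nematode trophic_group and cp_class annotations")
    ba1 = _trophic_sum(ct, (ann["trophic_group"] == "bacterivore") & (ann["cp_class"] == 1))
    fu2 = _trophic_sum(ct, (ann["trophic_group"] == "fungivore") & (ann["cp_class"] == 2))
    den = 3.2 * ba1 + 0.8 * fu2
    out = 100.0 * 0.8 * fu2 / den.where(den > 0)
    return out.rename("NCI")


def pci(ct: CommunityTable) -> pd.Series:
    """Protozoa channel index: fungivore:bacterivore relative abundance.

    Taxa annotated "other" are excluded from both numerator and
    denominator; missing when a sample has no bacterivore reads.
    """
    if ct.annotations is None or "feeding_habit" not in ct.annotations.columns:
        raise ValidationError("PCI needs protozoa feeding_habit annotations")
    fh = ct.annotations["feeding_habit"]
    f = _trophic_sum(ct, fh == "fungivore")
    b = _trophic_sum(ct, fh == "bacterivore")
    out = f / b.where(b > 0)
    if out.isna().any():
        logger.warning("PCI undefined (no bacterivores) for %d samples",
                       int(out.isna().sum()))
    return out.rename("PCI")


def substrate_indices(substrate: pd.DataFrame) -> pd.DataFrame:
    """Substrate C:N stoichiometry and C decomposability indices.

    TOC:TN and DOC:DN as ratios; DOC:TOC and CKMnO4:TOC as percentages.
    """
    for col in ("TOC", "TN", "DOC", "DN", "CKMnO4"):
        if col not in substrate.columns:
            raise ValidationError(f"substrate table missing column {col!r}")
        if (substrate[col] <= 0).any():
            raise ValidationError(f"nonpositive values in substrate column {col!r}")
    out = pd.DataFrame(index=substrate.index)
    out["TOC_TN"] = substrate["TOC"] / substrate["TN"]
    out["DOC_DN"] = substrate["DOC"] / substrate["DN"]
    out["DOC_TOC_pct"] = 100.0 * substrate["DOC"] / substrate["TOC"]
    out["CKMnO4_TOC_pct"] = 100.0 * substrate["CKMnO4"] / substrate["TOC"]
    return out


def zscore(values: pd.Series) -> pd.Series:
    """Standardize to mean 0, sd 1 (n-1); an sd of 0 yields all zeros."""
    if len(values) < 2:
        raise ValidationError("z-scoring needs at least 2 samples")
    sd = values.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        return pd.Series(0.0, index=values.index, name=values.name)
    return (values - values.mean()) / sd


def zscore_aggregate(per_group: dict[str, pd.Series]) -> pd.Series:
    """Average of per-group z-scores, the whole-community summary statistic.

    Each group's metric is z-scored across samples, then averaged
    element-wise over groups; a zero-variance group contributes zeros.
    """
    if not per_group:
        raise ValidationError("no group metrics supplied")
    items = list(per_group.values())
    ref = set(items[0].index)
    for s in items[1:]:
        if set(s.index) != ref:
            raise ValidationError("group metrics cover different sample sets")
    z = pd.concat([zscore(s.loc[items[0].index]) for s in items], axis=1)
    return z.mean(axis=1).rename("avg_z")


#: substrate-table columns holding per-group community sizes
ABUNDANCE_COLUMNS = {
    "bacteria": "gene_copies_bacteria",
    "fungi": "gene_copies_fungi",
    "protozoa": "abundance_protozoa",
    "nematode": "abundance_nematode",
}


def foodweb_index_table(
    communities: dict[str, CommunityTable],
    substrate: pd.DataFrame | None = None,
    depths: dict[str, int] | None = None,
    seed: int = 1,
) -> pd.DataFrame:
    """All micro-food-web features as one per-sample table.

    Per group: rarefied richness/Shannon/Pielou and composition (PCo1 of
    Bray-Curtis on relative abundances). Channel indices NCR/NCI (nematode,
    free-living, rarefied to 100 by default), PCI (protozoa) and — when a
    substrate table is supplied — F:B, substrate ratios and community
    sizes. Whole-community columns: avg_pco1 and the z-score aggregates of
    abundance, richness, evenness and Shannon.
    """
    from .ordination import average_pco1, bray_curtis, pcoa

    depths = dict(depths or {})
    out = pd.DataFrame(index=next(iter(communities.values())).counts.index)
    ordinations = {}
    alphas = {}
    for group, ct in communities.items():
        work = free_living(ct) if group == "nematode" else ct
        depth = depths.get(group, NEMATODE_DEPTH if group == "nematode" else None)
        rare = rarefy(work, depth=depth, seed=seed)
        alpha = alpha_diversity(rare)
        alphas[group] = alpha
        for col in alpha.columns:
            out[f"{group}_{col}"] = alpha[col]
        ordinations[group] = pcoa(bray_curtis(rare.counts, relative=True))
        out[f"{group}_pco1"] = ordinations[group].pco1
        if group == "nematode":
            out["NCR"] = ncr(rare)
            out["NCI"] = nci(rare)
        if group == "protozoa":
            out["PCI"] = pci(rare)
    out["avg_pco1"] = average_pco1(ordinations)
    for metric, col in (("richness", "avg_z_richness"),
                        ("shannon", "avg_z_shannon"),
                        ("pielou", "avg_z_evenness")):
        out[col] = zscore_aggregate(
            {g: a[metric] for g, a in alphas.items()}
        )
    if substrate is not None:
        out["FB"] = fb_ratio(substrate)
        out = out.join(substrate_indices(substrate))
        abundances = {
            g: substrate[col]
            for g, col in ABUNDANCE_COLUMNS.items()
            if col in substrate.columns
        }
        for g, col in ABUNDANCE_COLUMNS.items():
            if col in substrate.columns:
                out[col] = substrate[col]
        for pool in ("TOC", "DOC", "CKMnO4", "TN", "DN"):
            if pool in substrate.columns:
                out[pool] = substrate[pool]
        if abundances:
            out["avg_z_abundance"] = zscore_aggregate(abundances)
    return out
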