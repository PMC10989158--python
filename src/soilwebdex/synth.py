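"""Synthetic data with the statistical structure the methodology assumes.

The generator emulates a 2-treatment (arable vs restored natural) x
2-season (June, September) x 4-plot design, n = 16 samples. Per sample it
draws

* a substrate table (TOC, DOC, CKMnO4, TN, DN, gene copies, microfaunal
  abundances) with treatment offsets;
* four community count tables (bacteria, fungi, protozoa at ASV level,
  nematodes at genus level) from a Dirichlet-multinomial whose base
  composition, evenness and fungal-channel tilt respond to treatment;
* guild annotations (nematode trophic group and cp class, protozoa
  feeding habit), fixed per taxon;
* eight enzyme activities as positive log-linear mixtures of the latent
  substrate, abundance, channel and diversity signals plus lognormal
  noise — so gross activity tracks TOC and community size, NAG:LAP tracks
  the fungal share, BG:NAG runs inversely with substrate C:N, BG:PHOX
  with C decomposability, and enzyme-profile evenness tracks community
  diversity, all by construction.

Every planted parameter is returned in ``ground_truth``. The Dirichlet-
multinomial is a testing harness with one evenness dial, not a claim
about soil ecology. Same seed, same config => bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_tables import ActivityTable, CommunityTable, ValidationError

TREATMENTS = ("arable", "natural")
SEASONS = ("June", "September")

ENZYME_BASE = {
    "AG": 20.0, "BG": 120.0, "CB": 35.0, "XS": 25.0,
    "NAG": 60.0, "LAP": 180.0, "PHOX": 900.0, "PEOX": 1400.0,
}

#: treatment multipliers (natural / arable) for substrate pools, matching
#: the reported land-use restoration responses of this system
SUBSTRATE_SHIFT = {"TOC": 1.929, "DOC": 1.634, "CKMnO4": 1.509,
                   "TN": 1.332, "DN": 1.267}
SUBSTRATE_BASE = {"TOC": 6.7, "DOC": 0.30, "CKMnO4": 1.2,
                  "TN": 1.07, "DN": 0.045}

#: treatment multipliers for community sizes (gene copies / individuals)
ABUNDANCE_SHIFT = {"bacteria": 1.837, "fungi": 2.452,
                   "protozoa": 1.588, "nematode": 2.401}
ABUNDANCE_BASE = {"bacteria": 1.0e9, "fungi": 8.0e7,
                  "protozoa": 2.0e4, "nematode": 420.0}


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults are the study-like condition."""

    seed: int = 0
    n_plots: int = 4
    n_taxa: dict = field(default_factory=lambda: {
        "bacteria": 300, "fungi": 150, "protozoa": 100, "nematode": 25})
    depth: dict = field(default_factory=lambda: {
        "bacteria": 5000, "fungi": 4000, "protozoa": 3000, "nematode": 200})
    #: evenness dial: natural-treatment Dirichlet base is flattened by
    #: this exponent (>1 -> higher Shannon/richness under natural)
    diversity_multiplier: float = 1.5
    #: natural/arable multiplier on the fungal channel (applies to F:B)
    channel_shift: float = 1.33
    #: log-scale tilt of fungivorous vs bacterivorous taxa per unit of
    #: the standardized fungal-share latent
    nematode_channel_coupling: float = 0.8
    protozoa_channel_coupling: float = 0.4
    #: strength of the enzyme <- (substrate, abundance) activity coupling
    activity_coupling: float = 0.5
    #: strength of the NAG/LAP <- fungal-share coupling
    enzyme_channel_coupling: float = 0.35
    #: strength of the BG <- C:N and BG:PHOX <- decomposability couplings
    stoichiometry_coupling: float = 0.35
    #: enzyme-profile spread shrinks with community diversity at this rate
    evenness_coupling: float = 0.5
    #: baseline per-enzyme multiplicative spread (log scale)
    enzyme_spread: float = 0.7
    #: residual lognormal noise sd on activities (log scale)
    noise_sd: float = 0.15
    #: lognormal noise on substrate pools and community sizes (log scale)
    substrate_noise: float = 0.10
    #: between-treatment composition shift (log-scale sd of the fixed
    #: per-treatment taxon offsets)
    composition_shift: float = 0.8
    #: Dirichlet total concentration (higher -> less plot-to-plot scatter)
    concentration: float = 150.0

    def __post_init__(self) -> None:
        if self.depth.get("nematode", 0) < 100:
            raise ValidationError("nematode depth must be >= 100")
        for name in ("diversity_multiplier", "channel_shift"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


def _null_config(seed: int = 0, **kw) -> SynthConfig:
    return SynthConfig(
        seed=seed,
        diversity_multiplier=1.0, channel_shift=1.0,
        nematode_channel_coupling=0.0, protozoa_channel_coupling=0.0,
        activity_coupling=0.0, enzyme_channel_coupling=0.0,
        stoichiometry_coupling=0.0, evenness_coupling=0.0,
        composition_shift=0.0, **kw)


_SMALL_SIZES = dict(
    n_taxa={"bacteria": 60, "fungi": 40, "protozoa": 30, "nematode": 20},
    depth={"bacteria": 2000, "fungi": 1500, "protozoa": 1000, "nematode": 200},
)

PRESETS = {
    "paper-like": lambda seed=0: SynthConfig(seed=seed),
    "paper-like-small": lambda seed=0: SynthConfig(seed=seed, **_SMALL_SIZES),
    "null": _null_config,
    "null-small": lambda seed=0: _null_config(seed=seed, **_SMALL_SIZES),
    "strong-signal": lambda seed=0: SynthConfig(
        seed=seed, activity_coupling=0.8, enzyme_channel_coupling=0.6,
        stoichiometry_coupling=0.6, evenness_coupling=0.8, noise_sd=0.08),
}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _metadata(cfg: SynthConfig) -> pd.DataFrame:
    rows = []
    for t in TREATMENTS:
        for s in SEASONS:
            for p in range(1, cfg.n_plots + 1):
                rows.append((f"{t[:3]}-{s[:3]}-{p}", t, s, p))
    return pd.DataFrame(
        rows, columns=["sample_id", "treatment", "season", "plot"]
    ).set_index("sample_id")


def _substrate(cfg: SynthConfig, md: pd.DataFrame,
               rng: np.random.Generator) -> pd.DataFrame:
    n = len(md)
    natural = (md["treatment"] == "natural").to_numpy()
    september = (md["season"] == "September").to_numpy()
    sub = pd.DataFrame(index=md.index)
    season_dip = np.where(september, 0.95, 1.0)
    for pool, base in SUBSTRATE_BASE.items():
        shift = np.where(natural, SUBSTRATE_SHIFT[pool], 1.0)
        noise = np.exp(rng.normal(0.0, cfg.substrate_noise, n))
        sub[pool] = base * shift * season_dip * noise
    for group, base in ABUNDANCE_BASE.items():
        shift = np.where(natural, ABUNDANCE_SHIFT[group], 1.0)
        if group == "fungi":
            shift = shift * np.where(natural, cfg.channel_shift, 1.0)
        noise = np.exp(rng.normal(0.0, cfg.substrate_noise, n))
        col = {"bacteria": "gene_copies_bacteria",
               "fungi": "gene_copies_fungi",
               "protozoa": "abundance_protozoa",
               "nematode": "abundance_nematode"}[group]
        sub[col] = base * shift * season_dip * noise
    return sub


def _annotations(group: str, taxa: list[str],
                 rng: np.random.Generator) -> pd.DataFrame | None:
    if group == "nematode":
        trophic = list(rng.choice(
            ["bacterivore", "fungivore", "omnivore-predator", "herbivore"],
            size=len(taxa), p=[0.40, 0.25, 0.20, 0.15]))
        # guarantee the guilds every channel index needs
        trophic[0], trophic[1] = "bacterivore", "bacterivore"
        trophic[2], trophic[3] = "fungivore", "fungivore"
        cp = []
        for tg in trophic:
            if tg == "bacterivore":
                cp.append(int(rng.choice([1, 2, 3], p=[0.5, 0.35, 0.15])))
            elif tg == "fungivore":
                cp.append(int(rng.choice([2, 3, 4], p=[0.7, 0.2, 0.1])))
            else:
                cp.append(int(rng.choice([3, 4, 5])))
        cp[0], cp[2] = 1, 2  # at least one Ba1 and one Fu2 genus
        return pd.DataFrame({"trophic_group": trophic, "cp_class": cp},
                            index=pd.Index(taxa, name="taxon"))
    if group == "protozoa":
        habit = rng.choice(["bacterivore", "fungivore", "other"],
                           size=len(taxa), p=[0.5, 0.3, 0.2])
        habit[0], habit[1] = "bacterivore", "fungivore"
        return pd.DataFrame({"feeding_habit": habit},
                            index=pd.Index(taxa, name="taxon"))
    return None


def _community(group: str, cfg: SynthConfig, md: pd.DataFrame,
               channel_z: np.ndarray, rng: np.random.Generator
               ) -> tuple[CommunityTable, np.ndarray]:
    """Draw one group's counts; returns the table and the per-sample
    Shannon of the latent (pre-multinomial) proportions."""
    n_taxa = cfg.n_taxa[group]
    prefix = {"bacteria": "bASV", "fungi": "fASV",
              "protozoa": "pASV", "nematode": "Genus"}[group]
    taxa = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    ann = _annotations(group, taxa, rng)
    base = rng.lognormal(0.0, 1.2, n_taxa)
    base /= base.sum()
    if group == "nematode":
        # fixed guild-level shares keep free-living individuals well above
        # the 100-count rarefaction floor at the configured depth
        guild_share = {"bacterivore": 0.40, "fungivore": 0.25,
                       "omnivore-predator": 0.15, "herbivore": 0.20}
        tg = ann["trophic_group"].to_numpy()
        for guild, share in guild_share.items():
            mask = tg == guild
            if mask.any():
                base[mask] = share * base[mask] / base[mask].sum()
        base /= base.sum()
    treat_offset = {
        t: np.exp(rng.normal(0.0, cfg.composition_shift, n_taxa))
        for t in TREATMENTS
    }
    coupling = {"nematode": cfg.nematode_channel_coupling,
                "protozoa": cfg.protozoa_channel_coupling}.get(group, 0.0)
    if ann is not None and coupling > 0:
        key = "trophic_group" if group == "nematode" else "feeding_habit"
        fung = (ann[key] == "fungivore").to_numpy()
        bact = (ann[key] == "bacterivore").to_numpy()
    else:
        fung = bact = np.zeros(n_taxa, dtype=bool)

    natural = (md["treatment"] == "natural").to_numpy()
    counts = np.empty((len(md), n_taxa), dtype=np.int64)
    latent_shannon = np.empty(len(md))
    for i, (sid, row) in enumerate(md.iterrows()):
        p = base * treat_offset[row["treatment"]]
        if natural[i]:
            # flatten -> higher evenness/richness under restoration
            p = p ** (1.0 / cfg.diversity_multiplier)
        if group == "nematode":
            # guild shares set at the sample level: the channel tilt moves
            # the fungivore:bacterivore balance while herbivores stay a
            # minor fraction, keeping free-living counts above the
            # 100-individual rarefaction floor
            t = np.exp(coupling * channel_z[i]) if coupling > 0 else 1.0
            tg = ann["trophic_group"].to_numpy()
            targets = {"bacterivore": 0.40 / t, "fungivore": 0.25 * t,
                       "omnivore-predator": 0.15, "herbivore": 0.20}
            total = sum(targets.values())
            for guild, share in targets.items():
                mask = tg == guild
                if mask.any():
                    p[mask] = (share / total) * p[mask] / p[mask].sum()
        elif coupling > 0:
            tilt = np.exp(coupling * channel_z[i])
            p = p * np.where(fung, tilt, 1.0) * np.where(bact, 1.0 / tilt, 1.0)
        p /= p.sum()
        pi = rng.dirichlet(cfg.concentration * p)
        pos = pi[pi > 0]
        latent_shannon[i] = -np.sum(pos * np.log(pos))
        counts[i] = rng.multinomial(cfg.depth[group], pi)
    table = CommunityTable(
        group=group,
        counts=pd.DataFrame(counts, index=md.index, columns=taxa),
        annotations=ann,
    )
    return table, latent_shannon


def _activities(cfg: SynthConfig, md: pd.DataFrame, sub: pd.DataFrame,
                diversity_z: np.ndarray, rng: np.random.Generator
                ) -> ActivityTable:
    n = len(md)
    s_toc = _zscore(np.log(sub["TOC"].to_numpy()))
    abund_cols = ["gene_copies_bacteria", "gene_copies_fungi",
                  "abundance_protozoa", "abundance_nematode"]
    s_abund = _zscore(np.log(sub[abund_cols].to_numpy()).mean(axis=1))
    s_cn = _zscore(np.log((sub["TOC"] / sub["TN"]).to_numpy()))
    s_dec = _zscore(np.log((sub["CKMnO4"] / sub["TOC"]).to_numpy()))
    s_channel = _zscore(np.log(
        (sub["gene_copies_fungi"] / sub["gene_copies_bacteria"]).to_numpy()))

    enzymes = list(ENZYME_BASE)
    loadings = rng.normal(0.0, 1.0, len(enzymes))
    loadings -= loadings.mean()
    act = np.empty((n, len(enzymes)))
    spread = cfg.enzyme_spread * np.exp(-cfg.evenness_coupling * diversity_z)
    common = cfg.activity_coupling * (0.6 * s_toc + 0.4 * s_abund)
    for j, e in enumerate(enzymes):
        log_a = np.log(ENZYME_BASE[e]) + common + spread * loadings[j]
        if e == "NAG":
            log_a = log_a + cfg.enzyme_channel_coupling * s_channel
        if e == "LAP":
            log_a = log_a - cfg.enzyme_channel_coupling * s_channel
        if e == "BG":
            log_a = (log_a - cfg.stoichiometry_coupling * s_cn
                     + cfg.stoichiometry_coupling * s_dec)
        act[:, j] = np.exp(log_a + rng.normal(0.0, cfg.noise_sd, n))
    return ActivityTable(pd.DataFrame(act, index=md.index, columns=enzymes))


def generate(config: SynthConfig) -> dict:
    """Generate one full input bundle plus the planted ground truth.

    Returns a dict with keys ``metadata``, ``communities`` (group ->
    CommunityTable), ``activity`` (ActivityTable), ``substrate``
    (DataFrame) and ``ground_truth``.
    """
    rng = np.random.default_rng(config.seed)
    md = _metadata(config)
    sub = _substrate(config, md, rng)
    channel_z = _zscore(np.log(
        (sub["gene_copies_fungi"] / sub["gene_copies_bacteria"]).to_numpy()))
    communities = {}
    latent_shannons = []
    for group in ("bacteria", "fungi", "protozoa", "nematode"):
        table, latent_h = _community(group, config, md, channel_z, rng)
        communities[group] = table
        latent_shannons.append(_zscore(latent_h))
    diversity_z = np.mean(latent_shannons, axis=0)
    activity = _activities(config, md, sub, diversity_z, rng)
    ground_truth = asdict(config)
    ground_truth.update(
        substrate_shift=dict(SUBSTRATE_SHIFT),
        abundance_shift=dict(ABUNDANCE_SHIFT),
        planted_positive=["gross_activity~TOC", "shannon_whole~avg_z_shannon",
                          "NAG_LAP~FB"],
        planted_negative=["BG_NAG~TOC_TN"],
        nag_lap_higher_in="natural" if config.channel_shift > 1 else None,
    )
    return {
        "metadata": md,
        "communities": communities,
        "activity": activity,
        "substrate": sub,
        "ground_truth": ground_truth,
    }


def write_bundle(bundle: dict, outdir) -> dict:
    """Write a generated bundle as the TSV inputs the pipeline consumes."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    md_path = outdir / "metadata.tsv"
    bundle["metadata"].to_csv(md_path, sep="\t", index_label="sample_id")
    paths["metadata"] = md_path
    act_path = outdir / "activity.tsv"
    bundle["activity"].values.to_csv(act_path, sep="\t", index_label="sample_id")
    paths["activity"] = act_path
    sub_path = outdir / "substrate.tsv"
    bundle["substrate"].to_csv(sub_path, sep="\t", index_label="sample_id")
    paths["substrate"] = sub_path
    for group, ct in bundle["communities"].items():
        cpath = outdir / f"{group}_counts.tsv"
        ct.counts.to_csv(cpath, sep="\t", index_label="sample_id")
        paths[f"{group}_counts"] = cpath
        if ct.annotations is not None:
            apath = outdir / f"{group}_annotations.tsv"
            ct.annotations.to_csv(apath, sep="\t", index_label="taxon")
            paths[f"{group}_annotations"] = apath
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(bundle["ground_truth"], indent=2, default=str))
    paths["ground_truth"] = gt_path
    return paths


# ---------------------------------------------------------------------------
# Canonical graph fixtures with analytically known metric values

def planted_two_block_table(seed: int = 0, n_samples: int = 16,
                            block_size: int = 5,
                            noise_sd: float = 0.05) -> pd.DataFrame:
    """Feature table whose correlation screen yields two modules.

    Features 1..block_size follow latent u, the rest follow an
    independent latent v, each with small additive noise — within-block
    Spearman correlations are near 1, between-block near 0.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, 1.0, n_samples)
    v = rng.normal(0.0, 1.0, n_samples)
    cols = {}
    for b, latent in (("A", u), ("B", v)):
        for i in range(block_size):
            cols[f"{b}{i + 1}"] = latent + rng.normal(0.0, noise_sd, n_samples)
    return pd.DataFrame(cols, index=[f"s{i + 1}" for i in range(n_samples)])


def generate_test_graphs() -> list[dict]:
    """Canonical graph fixtures with their exact metric values attached.

    Each entry holds ``name``, ``graph`` (networkx) and ``expected``
    (closed-form avgK/avgCC/GD/Con and friends, where defined).
    """
    import networkx as nx

    fixtures = []
    fixtures.append({
        "name": "K6",
        "graph": nx.complete_graph(6),
        "expected": {"avgK": 5.0, "avgCC": 1.0, "GD": 1.0, "Con": 1.0,
                     "robustness": 1.0},
    })
    fixtures.append({
        "name": "P4",
        "graph": nx.path_graph(4),
        "expected": {"avgK": 1.5, "avgCC": 0.0, "GD": 10.0 / 6.0, "Con": 0.5},
    })
    fixtures.append({
        "name": "P3",
        "graph": nx.path_graph(3),
        "expected": {"vulnerability": 1.0, "efficiency": 5.0 / 6.0},
    })
    fixtures.append({
        "name": "K4",
        "graph": nx.complete_graph(4),
        "expected": {"vulnerability": 0.0, "efficiency": 1.0},
    })
    fixtures.append({
        "name": "star6",
        "graph": nx.star_graph(5),
        "expected": {"robustness_half": 0.5},  # exact enumeration, remove 3 of 6
    })
    two_tri = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    fixtures.append({
        "name": "two_triangles",
        "graph": two_tri,
        "expected": {"n_modules": 2, "modularity": 0.5},
    })
    return fixtures
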