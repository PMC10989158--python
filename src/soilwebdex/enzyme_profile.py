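"""Exoenzyme profile indices.

Eight enzymes form the reference profile: four C-acquiring hydrolases
(AG, BG, CB, XS), two N-acquiring hydrolases (NAG, LAP) and two oxidases
(PHOX, PEOX). From them we compute

* ratio indices on raw activities: BG:NAG (enzymatic C:N stoichiometry),
  BG:PHOX (C decomposability), NAG:LAP (decomposition channel — NAG is
  mainly fungal, LAP mainly bacterial);
* gross activity: mean of per-enzyme standardized activities (each enzyme
  scaled to max 100 over the data set), a multifunctionality proxy;
* Shannon diversity H' = -sum p ln p of a chosen sub-profile;
* composition: PCo1 of the Bray-Curtis ordination of the per-sample
  activity proportions.

Standardization removes order-of-magnitude differences between enzymes
before any profile-level aggregation; ratio indices stay on the raw
activity scale where the enzymatic-stoichiometry literature defines them
(``ratios_on="standardized"`` is available for sensitivity analysis).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_tables import ActivityTable, ValidationError
from .ordination import bray_curtis, pcoa

logger = logging.getLogger(__name__)

#: named Shannon sub-profiles, resolved against enzyme classes
PROFILES = ("whole", "C-degrading", "hydrolase", "C-hydrolase")


def standardize(raw: ActivityTable) -> ActivityTable:
    """Scale each enzyme column to its data-set maximum = 100.

    s_ie = 100 * a_ie / max_i(a_ie). The maximum is taken over every
    sample in the table (all treatments and seasons together); split the
    table first for a narrower scope.
    """
    maxima = raw.values.max(axis=0)
    zero = maxima[maxima <= 0]
    if len(zero):
        raise ValidationError(
            f"enzyme {zero.index[0]!r} is zero in every sample; cannot standardize"
        )
    return ActivityTable(100.0 * raw.values / maxima, dict(raw.enzyme_class))


def ratio_index(table: ActivityTable, numerator: str, denominator: str) -> pd.Series:
    """Per-sample activity ratio numerator/denominator.

    Samples with zero denominator activity get a missing value.
    """
    for e in (numerator, denominator):
        if e not in table.values.columns:
            raise ValidationError(f"unknown enzyme {e!r}")
    num = table.values[numerator]
    den = table.values[denominator]
    out = num / den.where(den > 0)
    n_missing = int(out.isna().sum())
    if n_missing:
        logger.warning(
            "%s:%s undefined (zero %s) for %d samples",
            numerator, denominator, denominator, n_missing,
        )
    return out.rename(f"{numerator}_{denominator}")


def gross_activity(std: ActivityTable, enzymes: list[str] | None = None) -> pd.Series:
    """Mean standardized activity per sample over ``enzymes`` (default all)."""
    cols = list(enzymes) if enzymes is not None else std.enzymes
    if not cols:
        raise ValidationError("gross activity needs a nonempty enzyme subset")
    missing = set(cols) - set(std.enzymes)
    if missing:
        raise ValidationError(f"unknown enzymes {sorted(missing)}")
    return std.values[cols].mean(axis=1).rename("gross_activity")


def resolve_profile(std: ActivityTable, profile) -> list[str]:
    """Map a named sub-profile (or explicit enzyme list) to enzyme columns."""
    if not isinstance(profile, str):
        subset = list(profile)
    elif profile == "whole":
        subset = std.enzymes
    elif profile == "C-degrading":
        subset = std.enzymes_of_class("C-hydrolase", "oxidase")
    elif profile == "hydrolase":
        subset = std.enzymes_of_class("C-hydrolase", "N-hydrolase")
    elif profile == "C-hydrolase":
        subset = std.enzymes_of_class("C-hydrolase")
    else:
        raise ValidationError(f"unknown profile {profile!r}; use one of {PROFILES}")
    missing = set(subset) - set(std.enzymes)
    if missing:
        raise ValidationError(f"unknown enzymes {sorted(missing)}")
    if len(subset) < 2:
        raise ValidationError(f"profile {profile!r} resolves to fewer than 2 enzymes")
    return subset


def shannon(values: pd.DataFrame) -> pd.Series:
    """H' = -sum p ln p of each row, p renormalized within the row.

    Zero entries contribute 0 (the p ln p -> 0 limit); all-zero rows are
    missing.
    """
    x = values.to_numpy(dtype=float)
    sums = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = x / sums[:, None]
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    h[sums <= 0] = np.nan
    return pd.Series(h, index=values.index, name="shannon")


def enzyme_shannon(std: ActivityTable, profile="whole") -> pd.Series:
    """Shannon diversity of a sub-profile from standardized activities."""
    subset = resolve_profile(std, profile)
    name = profile if isinstance(profile, str) else "subset"
    return shannon(std.values[subset]).rename(f"shannon_{name}")


def enzyme_composition(std: ActivityTable) -> pd.Series:
    """PCo1 of the Bray-Curtis ordination of per-sample activity proportions."""
    props = std.values.div(std.values.sum(axis=1), axis=0)
    return pcoa(bray_curtis(props)).pco1.rename("pco1_composition")


def enzyme_index_table(raw: ActivityTable, ratios_on: str = "raw") -> pd.DataFrame:
    """All enzyme-profile indices as one per-sample table.

    Columns: BG_NAG, BG_PHOX, NAG_LAP, gross_activity, shannon_whole,
    shannon_Cdeg, shannon_hydrolase, shannon_Chydrolase, pco1_composition.
    """
    if ratios_on not in ("raw", "standardized"):
        raise ValidationError("ratios_on must be 'raw' or 'standardized'")
    std = standardize(raw)
    ratio_src = raw if ratios_on == "raw" else std
    out = pd.DataFrame(index=raw.values.index)
    out["BG_NAG"] = ratio_index(ratio_src, "BG", "NAG")
    out["BG_PHOX"] = ratio_index(ratio_src, "BG", "PHOX")
    out["NAG_LAP"] = ratio_index(ratio_src, "NAG", "LAP")
    out["gross_activity"] = gross_activity(std)
    out["shannon_whole"] = enzyme_shannon(std, "whole")
    out["shannon_Cdeg"] = enzyme_shannon(std, "C-degrading")
    out["shannon_hydrolase"] = enzyme_shannon(std, "hydrolase")
    out["shannon_Chydrolase"] = enzyme_shannon(std, "C-hydrolase")
    out["pco1_composition"] = enzyme_composition(std)
    return out
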