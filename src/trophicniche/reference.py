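"""Published summary tables for the Pearl River black amur bream study.

The raw individual-level data behind these summaries were never deposited, so
the printed group-level tables are themselves inputs to parts of the analysis:
group-mean diet proportions feed the Morisita overlap matrix, the group
isotope summaries parameterize the synthetic-data generator and the mixing
model's consumer pool, and the printed SEA values let the small-sample SEAc
correction be checked directly.

Groups are the four ontogenetic size classes of *Megalobrama terminalis*
(black amur bream); isotope values are ‰ (δ13C vs VPDB, δ15N vs atmospheric
N₂); diet percentages are gut-content composition means across individuals.
"""

from __future__ import annotations

import numpy as np

from .datatypes import SourceSet

GROUPS = ("small_juvenile", "large_juvenile", "sub_adult", "adult")

#: Gut-content percent-by-weight means (%W) per group; items below the
#: publication's listing threshold are omitted, so columns sum to ~100.
DIET_PERCENT_W: dict[str, dict[str, float]] = {
    "detritus":       dict(zip(GROUPS, (94.1, 84.5, 96.8, 92.7))),
    "Chaetophorales": dict(zip(GROUPS, (5.5, 1.4, 0.0, 0.0))),
    "Mytiloida":      dict(zip(GROUPS, (0.0, 13.8, 3.1, 7.2))),
    "Coscinodiscales": dict(zip(GROUPS, (0.2, 0.02, 0.08, 0.05))),
    "Araphidiales":   dict(zip(GROUPS, (0.2, 0.05, 0.04, 0.01))),
    "Ulvales":        dict(zip(GROUPS, (0.0, 0.1, 0.0, 0.0))),
}

#: Gut-content percent-by-number means (%N) per group (detritus excluded).
DIET_PERCENT_N: dict[str, dict[str, float]] = {
    "Coscinodiscales":    dict(zip(GROUPS, (53.6, 9.4, 45.0, 50.2))),
    "Chaetophorales":     dict(zip(GROUPS, (12.5, 43.4, 0.0, 0.0))),
    "Chlorococcales":     dict(zip(GROUPS, (11.7, 0.1, 16.0, 14.4))),
    "Mytiloida":          dict(zip(GROUPS, (0.0, 16.7, 0.02, 0.02))),
    "Araphidiales":       dict(zip(GROUPS, (5.9, 2.4, 11.7, 6.7))),
    "Chroococcales":      dict(zip(GROUPS, (0.1, 0.0, 0.0, 26.2))),
    "Osillatoriales":     dict(zip(GROUPS, (1.0, 0.0, 9.9, 0.0))),
    "Ulvales":            dict(zip(GROUPS, (0.0, 6.1, 0.0, 0.0))),
    "Biraphidinales":     dict(zip(GROUPS, (4.4, 21.8, 15.5, 1.1))),
    "Aulonoraphidinales": dict(zip(GROUPS, (9.3, 0.0, 0.5, 0.4))),
}

#: Isotope sample size and (mean, SD) of δ13C / δ15N per consumer group.
ISOTOPE_GROUP_STATS: dict[str, dict] = {
    "small_juvenile": dict(n=11, d13C=(-24.67, 1.75), d15N=(11.60, 2.75)),
    "large_juvenile": dict(n=12, d13C=(-25.53, 1.43), d15N=(12.54, 2.44)),
    "sub_adult":      dict(n=15, d13C=(-26.10, 1.52), d15N=(13.53, 2.69)),
    "adult":          dict(n=8,  d13C=(-25.58, 1.33), d15N=(14.57, 3.09)),
}

#: Trophic enrichment factors (mean, SD) ‰ applied uniformly to all sources:
#: the omnivorous diet (plant + animal material) motivates these values.
TEF = {"d13C": (1.3, 0.3), "d15N": (2.3, 0.18)}

#: Potential prey-source signatures (mean, SD) ‰; single-sample sources get
#: SD 0. Codes follow the study: C4_P riparian C4 plants, Psp Potamogeton sp.,
#: Mni Macrobrachium nipponense, Awo Anodonta woodiana, Lfo Limnoperna
#: fortunei, Sca Semisulcospira cancellata, Cfl Corbicula fluminea, Bsp
#: Bellamya sp., Bde benthic detritus.
SOURCE_STATS: dict[str, dict] = {
    "Zooplankton":   dict(d13C=(-30.25, 1.07), d15N=(9.95, 2.08)),
    "Phytoplankton": dict(d13C=(-27.94, 0.24), d15N=(8.21, 1.13)),
    "C4_P":          dict(d13C=(-13.29, 0.21), d15N=(4.06, 1.44)),
    "Psp":           dict(d13C=(-25.29, 3.26), d15N=(7.45, 2.43)),
    "Mni":           dict(d13C=(-26.97, 0.66), d15N=(15.95, 1.32)),
    "Awo":           dict(d13C=(-24.72, 0.65), d15N=(6.46, 0.04)),
    "Lfo":           dict(d13C=(-26.53, 0.0),  d15N=(4.96, 0.0)),
    "Sca":           dict(d13C=(-24.16, 0.0),  d15N=(9.51, 0.0)),
    "Cfl":           dict(d13C=(-30.27, 0.26), d15N=(11.99, 0.31)),
    "Bsp":           dict(d13C=(-22.28, 0.34), d15N=(4.42, 1.02)),
    "Bde":           dict(d13C=(-26.11, 1.20), d15N=(7.08, 1.50)),
    "Sediment":      dict(d13C=(-25.23, 0.39), d15N=(5.85, 0.23)),
}

#: Published per-group niche metrics (‰ / ‰² / nats where applicable).
NICHE_TABLE: dict[str, dict[str, float]] = {
    "TNW":             dict(zip(GROUPS, (0.058, 0.699, 0.862, 0.938))),
    "WIC_over_TNW":    dict(zip(GROUPS, (0.250, 0.951, 0.637, 0.610))),
    "diet_similarity": dict(zip(GROUPS, (0.339, 0.185, 0.375, 0.386))),
    "NR":              dict(zip(GROUPS, (9.49, 7.77, 10.07, 9.56))),
    "CR":              dict(zip(GROUPS, (5.54, 4.80, 6.13, 3.48))),
    "CD":              dict(zip(GROUPS, (2.61, 2.40, 2.47, 2.55))),
    "MNND":            dict(zip(GROUPS, (1.04, 1.37, 1.15, 1.69))),
    "TA":              dict(zip(GROUPS, (19.22, 21.74, 30.87, 17.52))),
    "SEA":             dict(zip(GROUPS, (9.446, 10.041, 11.240, 12.957))),
    "SEAc":            dict(zip(GROUPS, (10.496, 11.045, 12.104, 15.116))),
}

#: Published pairwise Morisita dietary overlap indices.
MORISITA_TABLE: dict[tuple[str, str], float] = {
    ("small_juvenile", "large_juvenile"): 0.982,
    ("small_juvenile", "sub_adult"): 0.997,
    ("small_juvenile", "adult"): 0.995,
    ("large_juvenile", "sub_adult"): 0.984,
    ("large_juvenile", "adult"): 0.993,
    ("sub_adult", "adult"): 0.998,
}

#: δ15N-vs-standard-length regression as published: δ15N = 8.90 + 0.02·SL.
LENGTH_REGRESSION = dict(intercept=8.90, slope=0.02, r_squared=0.133, n=46)


def source_set(tracers: tuple[str, str] = ("d13C", "d15N")) -> SourceSet:
    """The twelve potential prey sources with the study's TEFs as a SourceSet."""
    names = list(SOURCE_STATS)
    mean = np.array([[SOURCE_STATS[s][t][0] for t in tracers] for s in names])
    sd = np.array([[SOURCE_STATS[s][t][1] for t in tracers] for s in names])
    tef_mean = np.tile([TEF[t][0] for t in tracers], (len(names), 1))
    tef_sd = np.tile([TEF[t][1] for t in tracers], (len(names), 1))
    return SourceSet(names=names, tracers=list(tracers), mean=mean, sd=sd,
                     tef_mean=tef_mean, tef_sd=tef_sd)


def diet_profiles(basis: str = "mass"):
    """Group-mean diet-proportion profiles from the printed %W or %N table."""
    from .datatypes import DietProfile

    table = DIET_PERCENT_W if basis == "mass" else DIET_PERCENT_N
    labels = list(table)
    return {
        g: DietProfile(
            labels=labels,
            proportions=np.array([table[t][g] for t in labels]) / 100.0,
            basis=basis,
        )
        for g in GROUPS
    }
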