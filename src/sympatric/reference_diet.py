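"""Published diet-composition profiles for the two felids.

Percent ingested biomass (Bio), percent scat volume (Vol) and frequency of
occurrence (Occ) per prey category, as reported for jungle cats (17 scats,
dry season total) and leopard cats (130 scats: 57 cool-dry, 73 hot-dry) in
Cambodian dry deciduous forest. These serve as worked-example inputs for the
niche indices and as the default composition targets of the synthetic scat
generator. Values are percentages at the finest reported granularity
(Muridae split into small / large / unknown size classes); insects carry no
biomass entry.
"""

from __future__ import annotations

#: Category order used when rendering diet tables.
CATEGORY_ORDER = [
    "murid_small",
    "murid_large",
    "murid_unknown",
    "sciurid",
    "hare",
    "muntjac",
    "civet",
    "bird",
    "reptile",
    "crab",
    "insect",
]

JUNGLE_CAT_TOTAL = {
    "n_scats": 17,
    "bio": {
        "murid_small": 33.7,
        "murid_large": 17.6,
        "murid_unknown": 4.8,
        "sciurid": 15.3,
        "hare": 11.5,
        "bird": 8.4,
        "reptile": 8.0,
        "crab": 0.8,
    },
    "vol": {
        "murid_small": 40.9,
        "murid_large": 16.2,
        "murid_unknown": 5.0,
        "sciurid": 16.7,
        "hare": 4.3,
        "bird": 6.5,
        "reptile": 8.7,
        "crab": 0.9,
        "insect": 0.9,
    },
    "occ": {
        "murid_small": 64.7,
        "murid_large": 29.4,
        "murid_unknown": 5.9,
        "sciurid": 47.1,
        "hare": 11.8,
        "bird": 23.5,
        "reptile": 64.7,
        "crab": 11.8,
        "insect": 17.6,
    },
}

LEOPARD_CAT_COOL_DRY = {
    "n_scats": 57,
    "bio": {
        "murid_small": 44.2,
        "murid_large": 10.6,
        "murid_unknown": 14.4,
        "sciurid": 22.2,
        "civet": 5.2,
        "bird": 1.4,
        "reptile": 2.0,
    },
    "vol": {
        "murid_small": 50.4,
        "murid_large": 8.8,
        "murid_unknown": 13.7,
        "sciurid": 22.3,
        "civet": 1.7,
        "bird": 1.0,
        "reptile": 2.0,
        "insect": 0.2,
    },
    "occ": {
        "murid_small": 63.2,
        "murid_large": 15.8,
        "murid_unknown": 14.0,
        "sciurid": 28.1,
        "civet": 1.8,
        "bird": 5.3,
        "reptile": 22.8,
        "insect": 1.8,
    },
}

LEOPARD_CAT_HOT_DRY = {
    "n_scats": 73,
    "bio": {
        "murid_small": 52.0,
        "murid_large": 6.7,
        "murid_unknown": 17.2,
        "sciurid": 13.4,
        "muntjac": 4.1,
        "bird": 4.4,
        "reptile": 2.1,
    },
    "vol": {
        "murid_small": 58.2,
        "murid_large": 5.5,
        "murid_unknown": 16.1,
        "sciurid": 13.3,
        "muntjac": 1.3,
        "bird": 2.9,
        "reptile": 2.1,
        "insect": 0.6,
    },
    "occ": {
        "murid_small": 64.4,
        "murid_large": 8.2,
        "murid_unknown": 17.8,
        "sciurid": 20.5,
        "muntjac": 1.4,
        "bird": 8.2,
        "reptile": 15.1,
        "insect": 12.3,
    },
}

LEOPARD_CAT_TOTAL = {
    "n_scats": 130,
    "bio": {
        "murid_small": 48.6,
        "murid_large": 8.5,
        "murid_unknown": 15.9,
        "sciurid": 17.3,
        "muntjac": 2.3,
        "civet": 2.3,
        "bird": 3.1,
        "reptile": 2.1,
    },
    "vol": {
        "murid_small": 54.8,
        "murid_large": 6.9,
        "murid_unknown": 15.0,
        "sciurid": 17.2,
        "muntjac": 0.7,
        "civet": 0.7,
        "bird": 2.1,
        "reptile": 2.1,
        "insect": 0.4,
    },
    "occ": {
        "murid_small": 63.9,
        "murid_large": 11.5,
        "murid_unknown": 16.2,
        "sciurid": 23.8,
        "muntjac": 0.8,
        "civet": 0.8,
        "bird": 6.9,
        "reptile": 18.5,
        "insect": 8.5,
    },
}

#: Aggregated biomass rows as published: Muridae = small + large + unknown,
#: small rodent = Muridae + Sciuridae.
PUBLISHED_AGGREGATES_BIO = {
    "jungle_cat_total": {"muridae": 56.0, "small_rodent": 71.3},
    "leopard_cat_cool_dry": {"muridae": 69.2, "small_rodent": 91.4},
    "leopard_cat_hot_dry": {"muridae": 75.9, "small_rodent": 89.3},
    "leopard_cat_total": {"muridae": 72.9, "small_rodent": 90.2},
}

#: Published niche breadth values (Levins B on biomass proportions).
PUBLISHED_NICHE_BREADTH = {
    "jungle_cat_total": 5.09,
    "leopard_cat_cool_dry": 3.57,
    "leopard_cat_hot_dry": 3.06,
    "leopard_cat_total": 3.31,
}

#: Published Horn's overlap between the two felids' biomass profiles.
PUBLISHED_HORNS_R0 = 0.85

PROFILES = {
    "jungle_cat_total": JUNGLE_CAT_TOTAL,
    "leopard_cat_cool_dry": LEOPARD_CAT_COOL_DRY,
    "leopard_cat_hot_dry": LEOPARD_CAT_HOT_DRY,
    "leopard_cat_total": LEOPARD_CAT_TOTAL,
}
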