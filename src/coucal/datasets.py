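"""Published field estimates for the Usangu coucal system.

Reference numbers from the long-term field study of black coucals
(*Centropus grillii*, male-only care) and white-browed coucals
(*C. superciliosus*, biparental care) breeding sympatrically in the Usangu
wetland, Tanzania.  They serve two purposes: as worked-example inputs for
computations that are fully determined by printed tallies (prey-composition
posteriors, relative fledging mass), and as generating values for the
synthetic-data module so that simulated datasets resemble the real study.
"""

from __future__ import annotations

BLACK = "black"
WHITE_BROWED = "white-browed"
SPECIES = (BLACK, WHITE_BROWED)

#: Prey items delivered to nestlings, tallied over all focal observations
#: (black coucal: 76 nests; white-browed coucal: 54 nests).
PREY_COUNTS = {
    BLACK: {"grasshoppers": 489, "frogs": 96, "mantises": 88},
    WHITE_BROWED: {"grasshoppers": 197, "frogs": 94, "mantises": 25},
}

#: Typical adult body mass (g) per species and sex.
ADULT_MASS_G = {
    (BLACK, "female"): 165.9,
    (BLACK, "male"): 98.0,
    (WHITE_BROWED, "female"): 153.8,
    (WHITE_BROWED, "male"): 136.1,
}

#: Logistic growth-curve estimates per species and sex:
#: growth constant K (1/day), inflection point I (day), asymptotic mass A (g).
GROWTH_PARAMS = {
    (WHITE_BROWED, "female"): {"K": 0.369, "I": 6.3, "A": 97.2},
    (WHITE_BROWED, "male"): {"K": 0.375, "I": 6.2, "A": 93.5},
    (BLACK, "female"): {"K": 0.377, "I": 6.2, "A": 77.1},
    (BLACK, "male"): {"K": 0.364, "I": 5.8, "A": 66.9},
}

#: Random-effect standard deviations of the asymptote (g) and inflection
#: point (day) and their correlation, at the nest and the nestling level.
GROWTH_RANEF = {
    (BLACK, "female"): {
        "nest": {"sd_A": 9.3, "sd_I": 0.9, "corr": 0.8},
        "nestling": {"sd_A": 11.7, "sd_I": 0.4, "corr": 0.4},
    },
    (BLACK, "male"): {
        "nest": {"sd_A": 10.8, "sd_I": 0.9, "corr": 0.7},
        "nestling": {"sd_A": 5.6, "sd_I": 0.7, "corr": -0.2},
    },
    (WHITE_BROWED, "female"): {
        "nest": {"sd_A": 11.4, "sd_I": 0.6, "corr": 0.4},
        "nestling": {"sd_A": 14.5, "sd_I": 1.0, "corr": 0.6},
    },
    (WHITE_BROWED, "male"): {
        "nest": {"sd_A": 7.7, "sd_I": 0.8, "corr": 0.2},
        "nestling": {"sd_A": 10.8, "sd_I": 0.6, "corr": 0.5},
    },
}

#: Share of diurnal incubation checks at white-browed coucal nests in which
#: the male was the incubating bird (binomial mixed-model population median).
WB_MALE_INCUBATION_SHARE = 0.809

#: Back-transformed feeding-rate slope per SD of brood mass (log-link scale).
FEEDING_BROOD_MASS_SLOPE = 0.31

def relative_fledging_table() -> dict[tuple[str, str], float]:
    """Percent of adult body mass reached at the growth asymptote.

    Computed as ``100 * A / adult_mass`` per species and sex, rounded to one
    decimal (black coucal females fledge far lighter, relative to the adult
    mass of their own sex, than any other group).
    """
    from coucal.growth import relative_fledging_mass

    return {
        key: relative_fledging_mass(GROWTH_PARAMS[key]["A"], ADULT_MASS_G[key])
        for key in GROWTH_PARAMS
    }
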