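"""Published parameter estimates bundled as worked-example inputs.

Neighbourhood sizes and densities for four *Agaricia* coral taxa (two
within *A. agaricites*, AA1/AA2, and two within *A. humilis*, AH1/AH3)
from a published RADseq + photogrammetry survey of Curaçao fringing
reefs.  Each entry gives the central estimate with its 95% CI as
(central, low, high):

* ``D_c`` — census density of genets, genets/m^2
* ``D_e`` — effective density (sibship N_e / sampled area), genets/m^2
* ``NS_rousset`` — neighbourhood size from the Rousset a-hat IbD slope
* ``NS_loiselle`` — neighbourhood size from the Loiselle F IbD slope

Feeding any (NS, D) pair into :func:`ibdispersal.dispersal.sigma_distribution`
reproduces the corresponding published Monte-Carlo dispersal estimate.
Entries are ``None`` where the survey found no significant IbD slope.
"""

AGARICIA_SURVEY = {
    "AA1": {
        "scale_m": 30,
        "D_c": (0.26, 0.14, 0.62),
        "D_e": (0.11, 0.07, 0.17),
        "NS_rousset": (35, 4, 2309),
        "NS_loiselle": (44, 4, 6624),
    },
    "AA2": {
        "scale_m": 75,
        "D_c": (0.89, 0.58, 1.39),
        "D_e": (0.38, 0.20, 0.81),
        "NS_rousset": (758114, 9, 7.3e18),
        "NS_loiselle": (587, 13, 8.1e6),
    },
    "AH1": {
        "scale_m": 55,
        "D_c": (0.33, 0.22, 0.55),
        "D_e": (0.24, 0.13, 0.39),
        "NS_rousset": None,
        "NS_loiselle": (94, 9, 9202),
    },
    "AH3": {
        "scale_m": 33,
        "D_c": (0.22, 0.15, 0.57),
        "D_e": (0.39, 0.17, 0.82),
        "NS_rousset": None,
        "NS_loiselle": (23, 7, 197),
    },
}
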