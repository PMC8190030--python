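"""Physical constants, unit conventions and reference force scales.

Internal unit system (fixed pipeline-wide, conversions happen only at I/O
boundaries): forces in pN, lengths in nm, time in s, velocities in um/s,
frequencies in Hz, spring constants in pN/nm, energies in pN*nm.
"""

from __future__ import annotations

#: Boltzmann constant in pN*nm/K.
KB_PN_NM_PER_K = 1.380649e-2

#: Default measurement temperature (37 C, physiological incubation).
DEFAULT_TEMPERATURE_K = 310.15


def thermal_energy(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """kBT in pN*nm at the given temperature (~4.28 pN*nm at 37 C)."""
    return KB_PN_NM_PER_K * temperature_K


#: Cell-cell pairings studied: three fibroblast phenotypes from Dupuytren's
#: disease patients (NF normal, SF scar, DF myofibroblast) against themselves,
#: MDCK epithelial cells against themselves, and fibroblast-MDCK pairings.
CONDITIONS = (
    "NF-NF",
    "SF-SF",
    "DF-DF",
    "MDCK-MDCK",
    "NF-MDCK",
    "SF-MDCK",
    "DF-MDCK",
)

#: Treatment regimes: EGTA chelates calcium and abolishes cadherin binding;
#: cytochalasin D depolymerises actin; ML-7 inhibits myosin light-chain
#: kinase; DMSO is the drug vehicle control.
TREATMENTS = ("none", "EGTA", "DMSO", "cytochalasinD", "ML7")

#: Pulling (approach/retract) velocities of the rate series, um/s.
VELOCITIES_UM_PER_S = (3.0, 5.0, 7.5, 10.0)

#: Published median rupture forces (pN) per pairing and pulling velocity,
#: measured by AFM single-cell force spectroscopy on confluent monolayers.
#: The synthetic presets calibrate their bond kinetics so that the simulated
#: rupture-force median at 3 um/s matches the corresponding entry.
REFERENCE_MEDIANS_PN: dict[str, dict[float, float]] = {
    "NF-NF": {3.0: 51.91, 5.0: 73.40, 7.5: 97.18, 10.0: 117.39},
    "SF-SF": {3.0: 45.21, 5.0: 74.22, 7.5: 103.28, 10.0: 128.51},
    "DF-DF": {3.0: 35.71, 5.0: 58.23, 7.5: 83.54, 10.0: 103.05},
    "MDCK-MDCK": {3.0: 75.51, 5.0: 98.48, 7.5: 124.08, 10.0: 149.68},
    "NF-MDCK": {3.0: 55.85, 5.0: 70.48, 7.5: 91.44, 10.0: 111.28},
    "SF-MDCK": {3.0: 39.68, 5.0: 68.19, 7.5: 92.36, 10.0: 106.62},
    "DF-MDCK": {3.0: 46.70, 5.0: 63.62, 7.5: 83.20, 10.0: 99.42},
}

#: Reported relative change of the median rupture force after actin
#: depolymerisation (cytochalasin D median / matched control median).
#: The decrease is significant for every pairing.
CYTOCHALASIN_D_MEDIAN_RATIO: dict[str, float] = {
    "NF-NF": 0.502,
    "SF-SF": 0.522,
    "DF-DF": 0.530,
    "MDCK-MDCK": 0.571,
    "NF-MDCK": 0.448,
    "SF-MDCK": 0.264,
    "DF-MDCK": 0.388,
}

#: Relative change of the median after myosin inactivation (ML-7).  Only the
#: myofibroblast pairing (DF-DF, N-/OB-cadherin heterophilic bonds) shows a
#: significant change -- a near-doubling; the other pairings are reported as
#: unchanged, so their preset ratio is 1 and the small tabulated differences
#: are treated as sampling noise.
ML7_MEDIAN_RATIO: dict[str, float] = {"DF-DF": 1.874}
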