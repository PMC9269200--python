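"""Reference cohort statistics used as simulator defaults.

These are summary statistics of a clinical glaucoma-screening cohort of
207 patients (160 with two healthy eyes, 47 with bilateral primary
open-angle glaucoma) measured with a Spectralis peripapillary OCT scan:
per-sector mean RNFL thicknesses for each eye, and the per-group mean and
standard deviation of the inter-eye thickness difference
``delta = w_right - w_left`` (µm) in every sector and for the global
contour G.

The patient-level data behind these summaries are not public; the
synthetic cohort generator (:mod:`rnflasym.simulate`) is calibrated so
that cohorts it draws reproduce these summaries in expectation.
"""

from __future__ import annotations

N_HEALTHY = 160
N_GLAUCOMA = 47

#: Age in years, mean and SD per group.
AGE_MEAN_SD = {"healthy": (59.10, 12.70), "glaucoma": (70.15, 9.21)}
#: Male/female counts per group.
GENDER_COUNTS = {"healthy": (53, 107), "glaucoma": (19, 28)}

#: Dataset-level mean thickness (µm) per sector and eye, pooled over all
#: 207 patients.  These are the normalising constants of the
#: cohort-referenced asymmetry metrics.
SECTOR_MEAN_RIGHT = {
    "TS": 128.1691,
    "T": 68.7826,
    "TI": 130.0773,
    "NS": 101.2029,
    "N": 74.1932,
    "NI": 106.1353,
    "G": 93.9469,
}
SECTOR_MEAN_LEFT = {
    "TS": 126.3527,
    "T": 68.0531,
    "TI": 132.8454,
    "NS": 109.5266,
    "N": 70.9469,
    "NI": 106.6957,
    "G": 93.9710,
}

#: Inter-eye difference delta (µm): per-group mean per sector.
DELTA_MEAN = {
    "healthy": {
        "TS": 2.7563,
        "T": 2.1500,
        "TI": -2.3375,
        "NS": -7.5938,
        "N": 4.2875,
        "NI": -1.0625,
        "G": 0.6563,
    },
    "glaucoma": {
        "TS": -1.3830,
        "T": -4.1064,
        "TI": -4.2340,
        "NS": -10.8085,
        "N": -0.2979,
        "NI": 1.1489,
        "G": -2.3404,
    },
}

#: Inter-eye difference delta (µm): per-group sample SD per sector.
DELTA_SD = {
    "healthy": {
        "TS": 16.8122,
        "T": 9.6793,
        "TI": 14.9220,
        "NS": 16.6878,
        "N": 12.5123,
        "NI": 16.5372,
        "G": 6.5895,
    },
    "glaucoma": {
        "TS": 45.3539,
        "T": 20.1022,
        "TI": 51.8594,
        "NS": 34.9370,
        "N": 26.0576,
        "NI": 34.5989,
        "G": 25.8728,
    },
}

#: Per-group mean of |delta| (µm) per sector; under the zero-mean normal
#: model these follow the half-normal mean law mu = sigma * sqrt(2/pi).
ABS_DELTA_MEAN = {
    "healthy": {
        "TS": 12.7438,
        "T": 7.0125,
        "TI": 11.7500,
        "NS": 14.3938,
        "N": 10.0000,
        "NI": 12.8125,
        "G": 4.2188,
    },
    "glaucoma": {
        "TS": 34.1489,
        "T": 15.2979,
        "TI": 40.0213,
        "NS": 27.8298,
        "N": 17.3617,
        "NI": 26.7660,
        "G": 20.6383,
    },
}
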