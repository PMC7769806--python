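"""Published reference values for mainland-China TCM health resources, 2013–2017.

These are the printed national summary tables of the traditional-Chinese-
medicine (TCM) health-resource system over 31 province-level divisions
(derived from China Health Statistical Yearbook aggregates): yearly
resource totals and densities, Gini coefficients by population and by
geographic area, Theil-index decompositions, and the DEA-based Malmquist
productivity results.  Province-level raw data are not public in
machine-readable form, so these summaries serve as fixed inputs for
internal-consistency checks (decomposition identities, contribution
rates, frequency counts) rather than as test fixtures for re-estimation.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "density_reference",
    "gini_reference",
    "theil_reference",
    "theil_by_region_reference",
    "mpi_by_year_reference",
    "mpi_by_province_reference",
]

_YEARS = [2013, 2014, 2015, 2016, 2017]

# per-1,000-persons, per-1,000-km2, national total per input resource
_DENSITY = {
    "institutions": {
        "per_1000_persons": [0.0304, 0.0319, 0.0339, 0.0358, 0.0390],
        "per_1000_km2": [0.0436, 0.0453, 0.0483, 0.0514, 0.0563],
        "total": [41966, 43635, 46541, 49527, 54243],
    },
    "beds": {
        "per_1000_persons": [0.5836, 0.6414, 0.6966, 0.7475, 0.8170],
        "per_1000_km2": [0.8342, 0.9104, 0.9937, 1.0726, 1.1785],
        "total": [794160, 877255, 957523, 1033547, 1135615],
    },
    "staff": {
        "per_1000_persons": [0.4403, 0.4724, 0.5055, 0.5393, 0.5731],
        "per_1000_km2": [0.6217, 0.6706, 0.7211, 0.7739, 0.8268],
        "total": [599114, 646152, 694827, 745725, 796704],
    },
}

_GINI = {
    ("population", "institutions"): [0.2855, 0.2793, 0.2798, 0.2754, 0.2644],
    ("population", "beds"): [0.1020, 0.1074, 0.1089, 0.1130, 0.1166],
    ("population", "staff"): [0.1080, 0.1090, 0.1080, 0.1028, 0.1024],
    ("area", "institutions"): [0.5888, 0.5821, 0.5866, 0.5905, 0.5970],
    ("area", "beds"): [0.6199, 0.6177, 0.6175, 0.6181, 0.6156],
    ("area", "staff"): [0.6751, 0.6738, 0.6710, 0.6661, 0.6671],
}

# total Theil index with its within-group (intra) and between-group (inter)
# components, per resource and year
_THEIL = {
    "institutions": {
        "T": [0.2250, 0.2229, 0.2266, 0.2287, 0.2341],
        "T_intra": [0.2241, 0.2226, 0.2266, 0.2287, 0.2336],
        "T_inter": [0.0009, 0.0003, 0.0001, 0.0000, 0.0006],
    },
    "beds": {
        "T": [0.1896, 0.1909, 0.1897, 0.1922, 0.1922],
        "T_intra": [0.1763, 0.1791, 0.1779, 0.1812, 0.1823],
        "T_inter": [0.0134, 0.0117, 0.0117, 0.0109, 0.0099],
    },
    "staff": {
        "T": [0.2386, 0.2370, 0.2313, 0.2278, 0.2311],
        "T_intra": [0.1923, 0.1961, 0.1933, 0.1932, 0.1982],
        "T_inter": [0.0462, 0.0409, 0.0381, 0.0346, 0.0329],
    },
    "outpatient_visits": {
        "T": [0.2887, 0.2911, 0.2891, 0.2924, 0.2912],
        "T_intra": [0.2082, 0.2083, 0.2082, 0.2120, 0.2157],
        "T_inter": [0.0805, 0.0828, 0.0808, 0.0804, 0.0756],
    },
    "discharged_patients": {
        "T": [0.2344, 0.2307, 0.2319, 0.2542, 0.2299],
        "T_intra": [0.2222, 0.2196, 0.2217, 0.2441, 0.2224],
        "T_inter": [0.0122, 0.0111, 0.0101, 0.0101, 0.0075],
    },
}

_THEIL_BY_REGION = {
    "institutions": {
        "eastern": [0.2117, 0.2153, 0.2153, 0.2357, 0.2597],
        "middle": [0.0621, 0.0588, 0.0646, 0.0632, 0.0568],
        "western": [0.3405, 0.3372, 0.3341, 0.3301, 0.3248],
    },
    "beds": {
        "eastern": [0.1940, 0.1966, 0.1972, 0.2028, 0.2086],
        "middle": [0.0859, 0.0931, 0.0964, 0.0973, 0.0969],
        "western": [0.2440, 0.2421, 0.2346, 0.2372, 0.2333],
    },
    "staff": {
        "eastern": [0.2062, 0.2066, 0.1996, 0.2104, 0.2157],
        "middle": [0.0920, 0.0985, 0.1030, 0.0996, 0.1034],
        "western": [0.2992, 0.3012, 0.2937, 0.2783, 0.2827],
    },
    "outpatient_visits": {
        "eastern": [0.1972, 0.1969, 0.1967, 0.2016, 0.2074],
        "middle": [0.0814, 0.0865, 0.0913, 0.0981, 0.1007],
        "western": [0.3320, 0.3319, 0.3251, 0.3321, 0.3216],
    },
    "discharged_patients": {
        "eastern": [0.2391, 0.2400, 0.2410, 0.3192, 0.2459],
        "middle": [0.1362, 0.1384, 0.1421, 0.1374, 0.1399],
        "western": [0.2870, 0.2748, 0.2759, 0.2699, 0.2721],
    },
}

# annual Malmquist geometric means over the 31 DMUs (per adjacent pair)
_MPI_BY_YEAR = {
    "2013-2014": {"effch": 1.000, "techch": 1.012, "pech": 1.000, "sech": 1.000, "tfpch": 1.012},
    "2014-2015": {"effch": 1.000, "techch": 0.985, "pech": 1.000, "sech": 1.000, "tfpch": 0.985},
    "2015-2016": {"effch": 1.000, "techch": 1.020, "pech": 1.000, "sech": 1.000, "tfpch": 1.020},
    "2016-2017": {"effch": 1.000, "techch": 1.007, "pech": 1.000, "sech": 1.000, "tfpch": 1.007},
}

# per-province Malmquist component means over the four adjacent pairs
_MPI_BY_PROVINCE = [
    ("Beijing", 1.000, 0.942, 1.000, 1.000, 0.942),
    ("Tianjin", 0.999, 0.956, 1.001, 0.998, 0.954),
    ("Hebei", 1.036, 0.945, 1.023, 1.013, 0.979),
    ("Shanxi", 1.024, 0.953, 1.013, 1.010, 0.975),
    ("Inner Mongolia", 0.989, 0.967, 1.005, 0.984, 0.957),
    ("Liaoning", 0.997, 0.955, 0.989, 1.007, 0.952),
    ("Jilin", 1.013, 0.951, 1.002, 1.010, 0.964),
    ("Heilongjiang", 0.987, 0.953, 0.982, 1.005, 0.941),
    ("Shanghai", 1.000, 0.982, 1.000, 1.000, 0.982),
    ("Jiangsu", 1.019, 0.976, 1.018, 1.001, 0.995),
    ("Zhejiang", 1.032, 0.954, 1.000, 1.032, 0.985),
    ("Anhui", 0.951, 0.973, 1.005, 0.947, 0.926),
    ("Fujian", 1.057, 0.956, 1.007, 1.050, 1.010),
    ("Jiangxi", 1.016, 0.961, 1.012, 1.003, 0.976),
    ("Shandong", 1.040, 0.957, 1.006, 1.034, 0.995),
    ("Henan", 1.027, 0.981, 1.034, 0.994, 1.008),
    ("Hubei", 1.008, 0.977, 1.027, 0.982, 0.985),
    ("Hunan", 1.003, 0.971, 0.998, 1.005, 0.974),
    ("Guangdong", 1.018, 0.954, 1.000, 1.018, 0.971),
    ("Guangxi", 1.011, 0.961, 1.005, 1.006, 0.972),
    ("Hainan", 1.071, 0.928, 1.007, 1.063, 0.993),
    ("Chongqing", 0.930, 0.989, 0.989, 0.940, 0.920),
    ("Sichuan", 0.977, 0.998, 1.000, 0.977, 0.975),
    ("Guizhou", 0.991, 0.978, 1.002, 0.989, 0.969),
    ("Yunnan", 0.944, 0.988, 1.003, 0.941, 0.933),
    ("Tibet", 1.000, 0.908, 1.000, 1.000, 0.908),
    ("Shaanxi", 1.001, 0.954, 1.000, 1.000, 0.955),
    ("Gansu", 0.948, 0.984, 0.998, 0.950, 0.933),
    ("Qinghai", 1.018, 0.953, 1.000, 1.018, 0.971),
    ("Ningxia", 0.974, 0.955, 1.000, 0.974, 0.929),
    ("Xinjiang", 0.939, 0.973, 1.000, 0.939, 0.914),
]


def density_reference() -> pd.DataFrame:
    """Yearly national totals and densities per input resource."""
    rows = []
    for resource, cols in _DENSITY.items():
        for i, year in enumerate(_YEARS):
            rows.append(
                {
                    "year": year,
                    "resource": resource,
                    "total": cols["total"][i],
                    "per_1000_persons": cols["per_1000_persons"][i],
                    "per_1000_km2": cols["per_1000_km2"][i],
                }
            )
    return pd.DataFrame(rows)


def gini_reference() -> pd.DataFrame:
    """Yearly Gini coefficients by base (population/area) and resource."""
    rows = [
        {"year": y, "base": base, "resource": res, "gini": v}
        for (base, res), vals in _GINI.items()
        for y, v in zip(_YEARS, vals)
    ]
    return pd.DataFrame(rows)


def theil_reference() -> pd.DataFrame:
    """Yearly total/within/between Theil components per resource."""
    rows = []
    for res, cols in _THEIL.items():
        for i, y in enumerate(_YEARS):
            rows.append(
                {
                    "year": y,
                    "resource": res,
                    "T": cols["T"][i],
                    "T_intra": cols["T_intra"][i],
                    "T_inter": cols["T_inter"][i],
                }
            )
    return pd.DataFrame(rows)


def theil_by_region_reference() -> pd.DataFrame:
    """Yearly within-region Theil index t_g per resource and region."""
    rows = []
    for res, groups in _THEIL_BY_REGION.items():
        for g, vals in groups.items():
            for y, v in zip(_YEARS, vals):
                rows.append({"year": y, "resource": res, "region": g, "t_g": v})
    return pd.DataFrame(rows)


def mpi_by_year_reference() -> pd.DataFrame:
    """Annual Malmquist component means (geometric, over 31 DMUs)."""
    return pd.DataFrame(
        [{"pair": p, **vals} for p, vals in _MPI_BY_YEAR.items()]
    ).set_index("pair")


def mpi_by_province_reference() -> pd.DataFrame:
    """Per-province Malmquist component means over 2013–2017."""
    return pd.DataFrame(
        _MPI_BY_PROVINCE, columns=["dmu", "effch", "techch", "pech", "sech", "tfpch"]
    ).set_index("dmu")
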