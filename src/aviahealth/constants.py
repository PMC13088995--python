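"""Shared category labels used across all pipeline stages."""

# 5-year age bands partitioning [0, 95+]
AGE_BANDS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(0, 95, 5)
) + ("95+",)

#: midpoint age of each band, used by age-dependent rate schedules (95+ -> 97.5)
AGE_MIDPOINTS: dict[str, float] = {
    band: (lo + 2.5) for band, lo in zip(AGE_BANDS, range(0, 100, 5))
}

SEXES: tuple[str, str] = ("male", "female")

POLLUTANTS: tuple[str, ...] = ("CO2", "PM2.5", "CO", "SO2", "NO2")

#: pollutants that act locally on health (CO2 matters only for the carbon ledger)
LOCAL_POLLUTANTS: tuple[str, ...] = ("PM2.5", "CO", "SO2", "NO2")

#: the ten disease-pollutant categories: six PM2.5 causes assessed with the
#: GEMM, four gaseous-pollutant causes assessed with log-linear relative risks
DISEASES: tuple[str, ...] = (
    "stroke",
    "LC",
    "LRI",
    "COPD",
    "IHD",
    "T2DM",
    "CCVD-CO",
    "RD-NO2",
    "CCVD-SO2",
    "RD-SO2",
)

SCENARIOS: tuple[str, ...] = ("DAC-CCS", "DAC-CCU", "PSC-CCS", "PSC-CCU")

#: annual-mass to emission-rate conversion: tonnes/yr -> g/s
SECONDS_PER_YEAR: float = 365.25 * 24 * 3600.0
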