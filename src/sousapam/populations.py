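"""Field-reported vocalization statistics for the Xiamen Bay humpback dolphin
population (*Sousa chinensis*), used as the default parameter distributions of
the synthetic-scene generator.

Values are literature-reported descriptive statistics (mean, SD, observed
range) of echolocation-click and whistle acoustic parameters, split by the
West and East sub-regions of the bay and pooled ("total").
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ParamStat:
    """Mean ± SD and observed range of one acoustic parameter."""

    mean: float
    sd: float
    lo: float
    hi: float


#: Click parameters. Keys: peak frequency f_p (kHz), -3/-6/-10 dB bandwidths
#: (kHz), 95%-energy duration (us), peak-to-peak SPL (dB re 1 uPa).
CLICKS: dict[str, dict[str, ParamStat]] = {
    "total": {
        "fp_khz": ParamStat(86.4, 19.5, 31.5, 133.9),
        "bw3_khz": ParamStat(53.3, 14.6, 19.4, 130.6),
        "bw6_khz": ParamStat(81.5, 18.9, 30.1, 169.7),
        "bw10_khz": ParamStat(109.8, 23.3, 44.0, 212.7),
        "duration_us": ParamStat(22.3, 6.4, 6.9, 48.6),
        "spl_pp_db": ParamStat(162.8, 9.5, 123.8, 193.2),
    },
    "west": {
        "fp_khz": ParamStat(86.8, 19.4, 31.5, 131.6),
        "bw3_khz": ParamStat(53.7, 14.7, 19.4, 130.6),
        "bw6_khz": ParamStat(82.3, 18.7, 30.1, 169.7),
        "bw10_khz": ParamStat(110.2, 22.5, 44.0, 209.6),
        "duration_us": ParamStat(22.0, 6.2, 6.9, 45.1),
        "spl_pp_db": ParamStat(163.6, 8.3, 126.8, 193.2),
    },
    "east": {
        "fp_khz": ParamStat(85.4, 19.8, 32.0, 133.9),
        "bw3_khz": ParamStat(52.2, 14.3, 19.6, 113.9),
        "bw6_khz": ParamStat(79.4, 19.1, 33.5, 168.7),
        "bw10_khz": ParamStat(108.6, 25.3, 48.2, 212.7),
        "duration_us": ParamStat(23.1, 6.7, 8.7, 48.6),
        "spl_pp_db": ParamStat(160.7, 11.9, 123.8, 187.0),
    },
}

#: Whistle parameters: duration (ms), beginning/ending frequency, minimum and
#: maximum frequency, frequency range (kHz).
WHISTLES: dict[str, dict[str, ParamStat]] = {
    "total": {
        "duration_ms": ParamStat(247.6, 174.2, 21.4, 937.0),
        "bf_khz": ParamStat(5.9, 2.4, 3.1, 13.3),
        "ef_khz": ParamStat(6.4, 2.8, 2.4, 15.9),
        "minf_khz": ParamStat(5.2, 2.2, 2.2, 12.9),
        "maxf_khz": ParamStat(7.5, 2.7, 4.0, 15.9),
        "range_khz": ParamStat(2.4, 2.1, 0.1, 10.5),
    },
    "west": {
        "duration_ms": ParamStat(246.8, 179.7, 21.4, 937.0),
        "bf_khz": ParamStat(5.9, 2.2, 3.1, 13.3),
        "ef_khz": ParamStat(6.4, 2.9, 2.4, 15.9),
        "minf_khz": ParamStat(5.1, 2.1, 2.4, 12.9),
        "maxf_khz": ParamStat(7.6, 2.8, 4.0, 15.9),
        "range_khz": ParamStat(2.6, 2.2, 0.1, 10.5),
    },
    "east": {
        "duration_ms": ParamStat(250.3, 157.3, 25.1, 642.1),
        "bf_khz": ParamStat(6.1, 2.9, 3.2, 12.4),
        "ef_khz": ParamStat(6.4, 2.6, 4.1, 11.6),
        "minf_khz": ParamStat(5.5, 2.8, 2.2, 12.4),
        "maxf_khz": ParamStat(7.1, 2.6, 4.1, 11.6),
        "range_khz": ParamStat(1.8, 1.3, 0.4, 5.1),
    },
}

#: Whistle sample sizes and the two counts reported for shape proportions.
WHISTLE_COUNTS = {"total": 107, "west": 83, "east": 24, "constant": 43, "concave": 7}

#: Click sample sizes per sub-region.
CLICK_COUNTS = {"total": 33038, "west": 24033, "east": 9005}
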