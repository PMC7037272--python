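"""Bundled example data: the Odra River estuary organotin monitoring table.

Ten bottom-sediment samples from the Odra estuary (Szczecin Lagoon area,
NW Poland) with their physicochemical profiles and the TBT/TPhT
concentrations determined in the <0.063 mm fraction by the validated
QuEChERS LC-MS/MS method. Entries printed as "<5" are left-censored at the
5 ng/g TPhT quantification limit and load as ``below_lloq`` flags.
"""

from __future__ import annotations

import io

import pandas as pd

from .io_model import SedimentProfile, read_sediment_profiles
from .quantify_report import BELOW_LLOQ, QuantResult

_SEDIMENTS_CSV = """\
matrix_id,pH,conductivity,toc,n,h,avs,p,heavy_metals,pah,sand,silt,clay
S1,7.0,0.90,7.07,0.53,1.05,0.12,0.208,2399,9423,35,62,3
S2,6.9,1.13,6.53,0.6,1.16,0.4,0.302,2497,9828,27,70,3
S3,6.9,1.00,2.41,0.24,0.49,0.08,0.152,1213,2247,51,46,3
S4,6.7,0.95,8.81,0.66,1.24,0.35,0.297,2804,9625,30,67,3
S5,6.7,0.74,8.37,0.83,1.4,0.16,0.399,3123,no data,21,75,4
S6,6.6,8.00,7.83,1.04,1.38,0.44,0.137,1920,2019.4,35,63,2
S7,6.9,1.02,15.4,1.37,2.21,0.9,0.213,2814,73595,24,74,3
S8,6.7,1.07,7.67,0.75,1.42,0.38,0.794,3318,no data,34,63,3
S9,7.1,0.88,9.13,0.91,1.43,0.1,0.136,1704,no data,32,66,3
S10,6.8,1.15,7.57,0.82,1.51,0.27,0.385,3710,no data,14,82,4
"""

_RESULTS_CSV = """\
sample_id,localization,TBT,TPhT
S1,Szczecin Shipyard,3296,<5
S2,Gunica River,3884,<5
S3,Elevator Ewa,142,90
S4,Swieta River,1016,<5
S5,Dabie Lake,345,<5
S6,Piast Canal,213,<5
S7,Larpia River-Police,220,<5
S8,Szczecin Harbor,750,<5
S9,Szczecin-Dabie Marina Club,193,<5
S10,Szczecin-West Odra River,5263,9
"""


def odra_sediment_profiles() -> list[SedimentProfile]:
    """Physicochemical profiles of the ten monitored sediments.

    "no data" PAH entries (S5, S8-S10) load as missing, never as zero.
    """
    return read_sediment_profiles(io.StringIO(_SEDIMENTS_CSV))


def odra_quant_results() -> list[QuantResult]:
    """The reported TBT/TPhT concentrations as censoring-aware results."""
    df = pd.read_csv(io.StringIO(_RESULTS_CSV), dtype=str)
    results: list[QuantResult] = []
    for _, row in df.iterrows():
        for analyte in ("TBT", "TPhT"):
            raw = str(row[analyte]).strip()
            if raw.startswith("<"):
                results.append(
                    QuantResult(
                        sample_id=row["sample_id"],
                        analyte=analyte,
                        censored=BELOW_LLOQ,
                        localization=row["localization"],
                    )
                )
            else:
                results.append(
                    QuantResult(
                        sample_id=row["sample_id"],
                        analyte=analyte,
                        concentration=float(raw),
                        localization=row["localization"],
                    )
                )
    return results


__all__ = ["odra_sediment_profiles", "odra_quant_results"]
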