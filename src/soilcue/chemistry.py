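"""Microbial biomass and stoichiometric C/N imbalance from fumigation extraction.

Chloroform fumigation lyses microbial cells; the flush of dissolved organic C
and total dissolved N it releases into a K₂SO₄ extract, divided by an
extraction-efficiency coefficient, estimates microbial biomass C and N:

    MBC = (DOC_fumigated − DOC_unfumigated) / 0.45
    MBN = (TDN_fumigated − TDN_unfumigated) / 0.54

The stoichiometric C/N imbalance compares the resource stoichiometry a
community experiences with the stoichiometry of its own biomass:

    imbalance = (DOC / TDN) / (MBC / MBN)

where DOC and TDN are the unfumigated (plain soil extract) concentrations.
Values above 1 indicate C-rich / N-poor resources relative to microbial
demand. All concentrations must share a μg g⁻¹ dry-soil basis; the ratios are
then unit-free.
"""

from __future__ import annotations

import logging

import pandas as pd

from ._util import join_reasons

logger = logging.getLogger(__name__)

MBC_CONVERSION = 0.45
MBN_CONVERSION = 0.54

FUMIGATION_COLUMNS = [
    "sample_id",
    "doc_fumigated",
    "doc_unfumigated",
    "tdn_fumigated",
    "tdn_unfumigated",
]


def microbial_biomass(
    fumigated: float, unfumigated: float, conversion: float
) -> tuple[float, bool]:
    """Biomass concentration (μg g⁻¹) from a fumigation flush difference.

    Returns ``(biomass, clipped)``; a negative flush difference (possible
    under measurement noise) is clipped to 0 and flagged, since negative
    biomass is unphysical.
    """
    if not 0 < conversion <= 1:
        raise ValueError("conversion coefficient must be in (0, 1]")
    diff = fumigated - unfumigated
    if diff < 0:
        logger.warning("negative fumigation flush (%.4g) clipped to 0", diff)
        return 0.0, True
    return diff / conversion, False


def stoichiometric_imbalance(DOC: float, TDN: float, MBC: float, MBN: float) -> float:
    """(DOC/TDN) / (MBC/MBN); NaN when any denominator is non-positive."""
    if TDN <= 0 or MBN <= 0 or MBC <= 0:
        return float("nan")
    return (DOC / TDN) / (MBC / MBN)


def process_chemistry_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Derive MBC, MBN, ratios and imbalance for a table of extract pairs.

    ``pairs`` needs the columns in :data:`FUMIGATION_COLUMNS`; an optional
    ``pH`` column is passed through as a covariate. Output has one row per
    sample, sorted by sample_id, with columns MBC, MBN, DOC, TDN, r_cn
    (DOC/TDN), b_cn (MBC/MBN), imbalance and a ``reason`` flag column.
    Ratios with zero denominators come back as NaN with a reason code.
    """
    if pairs.empty:
        raise ValueError("fumigation table is empty")
    missing = set(FUMIGATION_COLUMNS) - set(pairs.columns)
    if missing:
        raise ValueError(f"fumigation table missing columns: {sorted(missing)}")
    dupes = pairs["sample_id"][pairs["sample_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate sample_id values: {sorted(set(dupes))}")

    rows = []
    for rec in pairs.to_dict("records"):
        reasons = []
        mbc, clipped_c = microbial_biomass(
            rec["doc_fumigated"], rec["doc_unfumigated"], MBC_CONVERSION
        )
        if clipped_c:
            reasons.append("negative_doc_flush_clipped")
        mbn, clipped_n = microbial_biomass(
            rec["tdn_fumigated"], rec["tdn_unfumigated"], MBN_CONVERSION
        )
        if clipped_n:
            reasons.append("negative_tdn_flush_clipped")
        doc = rec["doc_unfumigated"]
        tdn = rec["tdn_unfumigated"]
        r_cn = doc / tdn if tdn > 0 else float("nan")
        b_cn = mbc / mbn if mbn > 0 else float("nan")
        if tdn <= 0:
            reasons.append("tdn_zero")
        if mbn <= 0 or mbc <= 0:
            reasons.append("biomass_ratio_undefined")
        rows.append(
            {
                "sample_id": rec["sample_id"],
                "MBC": mbc,
                "MBN": mbn,
                "DOC": doc,
                "TDN": tdn,
                "r_cn": r_cn,
                "b_cn": b_cn,
                "imbalance": stoichiometric_imbalance(doc, tdn, mbc, mbn),
                "pH": rec.get("pH", float("nan")),
                "reason": join_reasons(*reasons),
            }
        )
    return pd.DataFrame(rows).sort_values("sample_id", ignore_index=True)
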