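"""Per-lesion feature assembly: radiomics + kinetics -> feature table.

Radiomic features are computed on the U2-phase frame of the ultrafast
series and on the first post-contrast frame of the standard series, inside
either the reference tumor mask or the simulated second-reader mask.  The
four modality kinetic features are appended, giving 1618 + 4 = 1622
predictors per (lesion, modality) row.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ufrad.kinetics import (
    KineticsConfig,
    cad_kinetics,
    extract_curve,
    find_hotspot,
    compute_u_phases,
    ultrafast_kinetics,
)
from ufrad.radiomics import extract_all
from ufrad.synthetic import LesionRecord

logger = logging.getLogger(__name__)

LABEL_COLUMNS = ("HR", "HER2", "subtype")


def _u2_frame_index(record: LesionRecord, cfg: KineticsConfig) -> int:
    roi = find_hotspot(record.ultrafast, record.tumor_mask, cfg.hotspot_diameter_mm)
    curve = extract_curve(record.ultrafast, roi)
    _, u2, _ = compute_u_phases(curve, record.ultrafast.schedule, cfg.onset_threshold)
    if u2 is None:
        logger.warning("%s: no onset; using mid-series frame", record.lesion_id)
        return record.ultrafast.schedule.n_frames // 2
    return u2


def lesion_features(
    record: LesionRecord,
    modality: str,
    mask_source: str = "truth",
    feature_set: str = "all",
    kinetics_cfg: KineticsConfig | None = None,
    n_bins: int = 32,
    wavelet: str = "coif1",
) -> pd.Series:
    """Feature vector of one lesion for one modality and mask source."""
    cfg = kinetics_cfg or KineticsConfig()
    mask = record.tumor_mask if mask_source == "truth" else record.reader2_mask
    parts: list[pd.Series] = []
    if feature_set in ("all", "radiomic"):
        if modality == "ultrafast":
            frame = record.ultrafast.data[_u2_frame_index(record, cfg)]
            spacing = record.ultrafast.spacing_mm
        else:
            n_pre = record.standard.schedule.n_precontrast
            frame = record.standard.data[n_pre]
            spacing = record.standard.spacing_mm
        parts.append(extract_all(frame, mask, spacing, n_bins=n_bins, wavelet=wavelet))
    if feature_set in ("all", "kinetic"):
        if modality == "ultrafast":
            kin = ultrafast_kinetics(record.ultrafast, mask, record.aorta_mask, cfg)
        else:
            kin = cad_kinetics(record.standard, mask, cfg.enh_threshold, cfg.delta)
        parts.append(pd.Series(kin.as_dict()))
    return pd.concat(parts)


def build_feature_table(
    records: list[LesionRecord],
    modality: str,
    mask_source: str = "truth",
    feature_set: str = "all",
    kinetics_cfg: KineticsConfig | None = None,
    n_bins: int = 32,
    wavelet: str = "coif1",
) -> pd.DataFrame:
    """Stack per-lesion feature vectors with label columns.

    Rows are lesions; columns are predictors followed by HR / HER2 /
    subtype labels, plus lesion_id / modality / mask_source metadata.
    """
    rows = []
    for rec in records:
        feats = lesion_features(
            rec, modality, mask_source, feature_set, kinetics_cfg, n_bins, wavelet
        )
        feats["lesion_id"] = rec.lesion_id
        for col in LABEL_COLUMNS:
            feats[col] = rec.labels.get(col)
        rows.append(feats)
    table = pd.DataFrame(rows).reset_index(drop=True)
    table.attrs["modality"] = modality
    table.attrs["mask_source"] = mask_source
    return table


def predictor_columns(table: pd.DataFrame) -> list[str]:
    meta = set(LABEL_COLUMNS) | {"lesion_id", "modality", "mask_source", "label"}
    return [c for c in table.columns if c not in meta]
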