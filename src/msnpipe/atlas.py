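"""Desikan-Killiany cortical parcellation labels.

The 68-region cortical atlas (34 regions per hemisphere, excluding the
corpus callosum "unknown" label) is the canonical node set for the
morphological similarity networks built by this package.  Labels follow
the ``{lh,rh}-<region>`` convention used by FreeSurfer's aparc tables.
"""

from __future__ import annotations

_DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: Canonical ordering: all left-hemisphere regions, then all right.
DK_ROI_LABELS: tuple[str, ...] = tuple(
    f"{hemi}-{region}" for hemi in ("lh", "rh") for region in _DK_REGIONS
)

N_ROIS: int = len(DK_ROI_LABELS)

assert N_ROIS == 68


def validate_roi_labels(labels) -> list[str]:
    """Check that *labels* are exactly the 68 atlas labels (any order).

    Returns the labels in canonical atlas order.  Raises ``ValueError``
    naming the offending labels otherwise.
    """
    labels = list(labels)
    seen = set(labels)
    if len(labels) != len(seen):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate ROI labels: {dupes}")
    missing = [l for l in DK_ROI_LABELS if l not in seen]
    unknown = [l for l in labels if l not in set(DK_ROI_LABELS)]
    if unknown:
        raise ValueError(f"unknown ROI labels (not in Desikan-Killiany atlas): {unknown}")
    if missing:
        raise ValueError(f"missing ROI labels: {missing}")
    return list(DK_ROI_LABELS)
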