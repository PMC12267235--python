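"""Cut taxonomies.

Every shot change (cut) is annotated with the shot scale before and after
the cut and the camera-angle variation across it.  Two taxonomies group
cuts for the variance analysis:

* **G1** looks only at the post-cut shot: its scale plus whether the
  camera angle changed by at least the on-axis threshold (30 degrees by
  default).  G1 labels partition the classifiable cuts; a full shot
  without angle variation has no G1 category and is reported as
  unclassified rather than guessed.
* **G2** describes the *relation* between the two shots.  Its categories
  overlap by construction (a close-up to close-up cut with a 40 degree
  angle change is simultaneously "close-up to close-up", "any to
  close-up" and "angle variation >= 30"), so classification returns a
  label *set* and a cut contributes to every matching category.

A coarser regrouping collapses cuts into same / increased / reduced shot
scale using the framing-size order close_up < medium < full < wide.
"""

from __future__ import annotations

import logging

from .io_formats import CutAnnotation, SHOT_SCALES

logger = logging.getLogger(__name__)

__all__ = [
    "ANGLE_THRESHOLD_DEG", "G1_LABELS", "G2_LABELS", "SCALE_GROUPS",
    "SCALE_ORDER", "classify_g1", "classify_g2", "scale_variation_group",
    "g2_scale_group", "classification_report",
]

#: Camera-angle change (degrees) from which a cut counts as "variation
#: >= 30"; below it a medium/wide post-cut shot is "on axis".
ANGLE_THRESHOLD_DEG = 30.0

G1_LABELS = (
    "medium_var_ge30", "medium_on_axis", "full_var_ge30",
    "closeup_var_ge30", "closeup_var_lt30", "wide_var_ge30", "wide_on_axis",
)

G2_LABELS = (
    "cu_to_cu", "ms_to_ms", "ws_to_ws", "any_to_cu", "any_to_ws",
    "cums_to_fsws", "fsws_to_cums", "var_lt30", "var_ge30",
)

SCALE_GROUPS = ("same_scale", "increased_scale", "reduced_scale")

#: Framing-size total order used to operationalise increased/reduced scale.
SCALE_ORDER = {"close_up": 0, "medium": 1, "full": 2, "wide": 3}

#: Scale-variation group of each scale-based G2 category (the two angle
#: categories carry no scale information and map to None).
G2_TO_SCALE_GROUP = {
    "cu_to_cu": "same_scale",
    "ms_to_ms": "same_scale",
    "ws_to_ws": "same_scale",
    "any_to_cu": "reduced_scale",
    "any_to_ws": "increased_scale",
    "cums_to_fsws": "increased_scale",
    "fsws_to_cums": "reduced_scale",
    "var_lt30": None,
    "var_ge30": None,
}


def _check_scale(scale: str) -> str:
    if scale not in SHOT_SCALES:
        raise ValueError(f"unknown shot scale {scale!r}; known: {SHOT_SCALES}")
    return scale


def classify_g1(annotation: CutAnnotation,
                angle_threshold: float = ANGLE_THRESHOLD_DEG) -> str | None:
    """G1 label of a cut, or None if the post-cut shot has no category.

    G1 depends only on the post-cut shot scale and the angle variation.
    The category table has no row for a full shot without angle
    variation, so that combination returns None (logged, and excluded
    from per-category model signals downstream).
    """
    post = _check_scale(annotation.post_scale)
    ge = annotation.angle_delta_deg >= angle_threshold
    if post == "close_up":
        return "closeup_var_ge30" if ge else "closeup_var_lt30"
    if post == "medium":
        return "medium_var_ge30" if ge else "medium_on_axis"
    if post == "wide":
        return "wide_var_ge30" if ge else "wide_on_axis"
    # full shot
    if ge:
        return "full_var_ge30"
    logger.info("cut %s/%s unclassified under G1 (full shot on axis)",
                annotation.film_id, annotation.cut_id)
    return None


def classify_g2(annotation: CutAnnotation,
                angle_threshold: float = ANGLE_THRESHOLD_DEG) -> frozenset[str]:
    """Set of all G2 categories a cut belongs to (never empty).

    Exactly one of ``var_lt30`` / ``var_ge30`` is always present, so the
    result is non-empty for every valid annotation.
    """
    pre = _check_scale(annotation.pre_scale)
    post = _check_scale(annotation.post_scale)
    labels: set[str] = set()
    if pre == post == "close_up":
        labels.add("cu_to_cu")
    if pre == post == "medium":
        labels.add("ms_to_ms")
    if pre == post == "wide":
        labels.add("ws_to_ws")
    if post == "close_up":
        labels.add("any_to_cu")
    if post == "wide":
        labels.add("any_to_ws")
    if pre in ("close_up", "medium") and post in ("full", "wide"):
        labels.add("cums_to_fsws")
    if pre in ("full", "wide") and post in ("close_up", "medium"):
        labels.add("fsws_to_cums")
    labels.add("var_ge30" if annotation.angle_delta_deg >= angle_threshold
               else "var_lt30")
    return frozenset(labels)


def scale_variation_group(annotation: CutAnnotation) -> str:
    """same_scale / increased_scale / reduced_scale of a cut (a partition)."""
    pre = SCALE_ORDER[_check_scale(annotation.pre_scale)]
    post = SCALE_ORDER[_check_scale(annotation.post_scale)]
    if pre == post:
        return "same_scale"
    return "increased_scale" if post > pre else "reduced_scale"


def g2_scale_group(g2_label: str) -> str | None:
    """Scale-variation group a G2 category falls into (None for the two
    pure-angle categories)."""
    try:
        return G2_TO_SCALE_GROUP[g2_label]
    except KeyError:
        raise KeyError(f"unknown G2 category {g2_label!r}") from None


def classification_report(annotations) -> "list[dict]":
    """Per-cut classification table (one dict per cut, CSV-ready)."""
    rows = []
    for ann in annotations:
        g1 = classify_g1(ann)
        g2 = classify_g2(ann)
        rows.append({
            "film_id": ann.film_id,
            "cut_id": ann.cut_id,
            "g1_label": g1 if g1 is not None else "unclassified",
            "g2_labels": ";".join(sorted(g2)),
            "scale_group": scale_variation_group(ann),
        })
    return rows
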