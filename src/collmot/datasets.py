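"""Small reference inputs used in worked examples.

``TISSUE_STIFFNESS_KPA`` holds published atomic-force-microscopy summary
statistics (mean +/- s.d. of the elastic modulus, in kPa) of normal and
cancerous vocal fold tissue, used to illustrate the stiffness fold change
between the two conditions.
"""

from __future__ import annotations

TISSUE_STIFFNESS_KPA = {
    "normal": {"mean": 0.751, "sd": 0.341, "n_curves": 366},
    "cancer": {"mean": 2.441, "sd": 1.479, "n_curves": 205},
}


def stiffness_fold_change(
    stiffness: dict | None = None,
    numerator: str = "cancer",
    denominator: str = "normal",
) -> float:
    """Fold change of mean tissue stiffness between two conditions."""
    table = TISSUE_STIFFNESS_KPA if stiffness is None else stiffness
    denom = table[denominator]["mean"]
    if denom <= 0:
        raise ValueError("denominator stiffness must be positive")
    return table[numerator]["mean"] / denom
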