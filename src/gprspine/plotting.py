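"""Simple coronal/sagittal spine views."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .geometry import SpineShape, csvl


def plot_spine(spine: SpineShape, ax_pair=None, label: str | None = None):
    """Coronal (y-z) and sagittal (x-z) projections of one posture."""
    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(6, 6), sharey=True)
    ax_cor, ax_sag = ax_pair
    y, x, z = spine.y, spine.x, spine.z
    name = label or spine.posture
    ax_cor.plot(y, z, "o-", ms=3, label=name)
    _, y0 = csvl(spine)
    ax_cor.axvline(y0, color="grey", lw=0.8, ls="--")
    ax_cor.set_xlabel("patient-left y (mm)")
    ax_cor.set_ylabel("cephalad z (mm)")
    ax_cor.set_title("coronal")
    ax_sag.plot(x, z, "o-", ms=3, label=name)
    ax_sag.set_xlabel("anterior x (mm)")
    ax_sag.set_title("sagittal")
    ax_cor.legend(fontsize=8)
    return ax_pair
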