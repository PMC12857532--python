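"""Basic DVH plotting."""

from __future__ import annotations

import numpy as np

from vmatrl.dose import DoseGrid
from vmatrl.phantoms import Phantom


def plot_dvh(dose: DoseGrid, phantom: Phantom, ax=None, max_rel_dose: float = 1.5):
    """Cumulative DVH curves (percent volume vs prescription-relative dose)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    levels = np.linspace(0.0, max_rel_dose, 200)
    for name, mask in sorted(phantom.masks.items()):
        d = np.asarray(dose.values)[mask]
        frac = [(d >= lv).mean() * 100.0 for lv in levels]
        ax.plot(levels * 100.0, frac, label=name)
    ax.set_xlabel("dose (% of prescription)")
    ax.set_ylabel("volume (%)")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    return ax
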