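"""Figure export for reinstatement maps, TF contrasts and band time courses."""

from __future__ import annotations

import os

import numpy as np

__all__ = ["plot_reinstatement_map", "plot_tf_contrast", "plot_figures"]


def _ax(ax):
    if ax is not None:
        return ax, None
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    return ax, fig


def plot_reinstatement_map(values, enc_times, ret_times, mask=None, ax=None,
                           title="reinstatement"):
    """Encoding-time x retrieval-time image; optional cluster contour."""
    ax, fig = _ax(ax)
    extent = [ret_times[0], ret_times[-1], enc_times[0], enc_times[-1]]
    vmax = np.nanmax(np.abs(values)) or 1.0
    im = ax.imshow(values, origin="lower", aspect="auto", extent=extent,
                   cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    if mask is not None and mask.any():
        ax.contour(ret_times, enc_times, mask.astype(float), levels=[0.5],
                   colors="k", linewidths=1)
    lo = max(enc_times[0], ret_times[0])
    hi = min(enc_times[-1], ret_times[-1])
    ax.plot([lo, hi], [lo, hi], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("retrieval time (s)")
    ax.set_ylabel("encoding time (s)")
    ax.set_title(title)
    if fig is not None:
        fig.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_tf_contrast(t_map, freqs, times, mask=None, ax=None, title="AR > IR"):
    ax, fig = _ax(ax)
    vmax = np.nanmax(np.abs(t_map)) or 1.0
    im = ax.pcolormesh(times, freqs, t_map, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                       shading="nearest")
    if mask is not None and mask.any():
        ax.contour(times, freqs, mask.astype(float), levels=[0.5], colors="k",
                   linewidths=1)
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title)
    if fig is not None:
        fig.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_figures(result, out_dir) -> list[str]:
    """Render the standard report panels from a pipeline result."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from .spectral import FrequencyGrid

    os.makedirs(out_dir, exist_ok=True)
    g = result.group
    written = []

    fig, axes = plt.subplots(1, 3, figsize=(14, 4), constrained_layout=True)
    for ax, key in zip(axes, ("AR", "IR", "surrogate")):
        vals = np.tanh(g["maps"][key]).mean(axis=0)
        plot_reinstatement_map(vals, g["enc_times"], g["ret_times"],
                               mask=g["conjunction_mask"] if key == "AR" else None,
                               ax=ax, title=key)
    path = os.path.join(out_dir, "reinstatement_maps.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
    freqs = FrequencyGrid.default().frequencies
    mask = g["res_tf"].significant_mask()
    plot_tf_contrast(g["res_tf"].stat_map, freqs, g["tf_times"], mask=mask, ax=ax)
    path = os.path.join(out_dir, "tf_contrast.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
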