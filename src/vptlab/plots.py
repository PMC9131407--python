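"""Basic diagnostic plots (radar-style orientation profiles, bias strips)."""

from __future__ import annotations

import numpy as np

from .design import ORIENTATIONS


def plot_orientation_profiles(profiles, participant_id=None, movement="pooled",
                              ax=None):
    """Polar plot of mean RT per orientation for each person location.

    If ``participant_id`` is None, plots the cohort mean profile.
    """
    import matplotlib.pyplot as plt

    sub = profiles[(profiles.movement == movement) & profiles.complete]
    if participant_id is not None:
        sub = sub[sub.participant_id == participant_id]
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.radians(list(ORIENTATIONS) + [ORIENTATIONS[0]])
    for loc, grp in sub.groupby("person_location"):
        vals = grp[list(ORIENTATIONS)].mean().to_numpy()
        ax.plot(theta, np.append(vals, vals[0]), label=f"person {loc}")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_title(f"orientation profiles ({movement})")
    ax.legend(loc="lower right", fontsize="small")
    return ax


def plot_bias_distributions(biases, kind="lr_bias", ax=None):
    """Strip plot of per-participant biases by condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = biases[(biases.movement != "pooled")].dropna(subset=[kind])
    labels, data = [], []
    for (mov, loc), grp in sub.groupby(["movement", "person_location"]):
        labels.append(f"{mov}\n{loc}")
        data.append(grp[kind].to_numpy())
    ax.violinplot(data, showmeans=True)
    ax.set_xticks(range(1, len(labels) + 1), labels, fontsize="small")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_ylabel(kind)
    return ax
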