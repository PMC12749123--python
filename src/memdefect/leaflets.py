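"""Assign lipid residues of a planar bilayer to the upper or lower leaflet.

The bilayer midplane is estimated from the mean z of all lipid phosphorus
atoms (falling back to all headgroup atoms for phosphorus-free systems such
as the coarse synthetic lipids); each lipid residue then goes to the leaflet
matching the sign of its mean headgroup height relative to the midplane.
"""

from __future__ import annotations

import numpy as np

from .models import Frame, LeafletAssignment
from .topology import LipidTopologySpec

__all__ = ["assign_leaflets"]


def assign_leaflets(frame: Frame, spec: LipidTopologySpec) -> LeafletAssignment:
    """Partition lipid residues into upper/lower leaflets.

    Invariant under rigid translations (z offsets shift the midplane with
    the lipids; xy translations are irrelevant). Ties go to the upper
    leaflet. Raises if the frame contains no lipid residues.
    """
    lipid_mask = np.array([spec.is_lipid(str(r)) for r in frame.res_names])
    if not lipid_mask.any():
        raise ValueError("frame contains no lipid residues known to the topology spec")

    elements = spec.resolve_elements(frame)
    head_mask = np.array([
        lipid_mask[i] and spec.role_of(str(frame.res_names[i]), str(frame.names[i])) == "headgroup"
        for i in range(frame.n_atoms)])
    if not head_mask.any():
        raise ValueError("no headgroup atoms found for any lipid residue")

    p_mask = lipid_mask & (elements == "P")
    ref_mask = p_mask if p_mask.any() else head_mask
    midplane = float(frame.positions[ref_mask, 2].mean())

    leaflet_of = {}
    keys = frame.residue_keys()
    for key in dict.fromkeys(keys[lipid_mask]):  # preserves order
        m = head_mask & (keys == key)
        if not m.any():  # lipid residue with no headgroup atoms present (e.g. carved)
            m = lipid_mask & (keys == key)
        mean_z = float(frame.positions[m, 2].mean())
        leaflet_of[key] = "upper" if mean_z >= midplane else "lower"
    return LeafletAssignment(leaflet_of=leaflet_of, midplane_z=midplane)
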