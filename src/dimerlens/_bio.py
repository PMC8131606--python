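"""Conversion helpers between package frames and biotite atom arrays."""

from __future__ import annotations

import numpy as np
import biotite.structure as _struc


def frame_to_atom_array(frame):
    arr = _struc.AtomArray(frame.n_atoms)
    arr.coord = frame.coords.astype(np.float32)
    arr.atom_name = frame.atom_name.astype("U6")
    arr.res_name = frame.res_name.astype("U5")
    arr.res_id = frame.res_id
    arr.chain_id = frame.chain_id.astype("U4")
    arr.element = frame.element.astype("U2")
    arr.set_annotation("hetero", frame.role_tag != "protein")
    return arr
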