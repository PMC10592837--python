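import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bcrtrees import (
    CellBundle,
    CloneAlignment,
    Rearrangement,
    simulate_clone,
)


def make_rearrangement(
    sequence_id,
    locus="IGH",
    seq="ACGTACGT",
    germ=None,
    cell_id=None,
    clone_id="clone1",
    v_call=None,
    j_call=None,
    junction_length=12,
):
    if v_call is None:
        v_call = "IGHV1-1*01" if locus == "IGH" else "IGKV1-1*01"
    if j_call is None:
        j_call = "IGHJ1*01" if locus == "IGH" else "IGKJ1*01"
    return Rearrangement(
        sequence_id=sequence_id,
        cell_id=cell_id,
        locus=locus,
        v_call=v_call,
        j_call=j_call,
        junction_length=junction_length,
        sequence_alignment=seq,
        germline_alignment=germ if germ is not None else seq,
        clone_id=clone_id,
    )


def make_bundle(cell_id, heavy_seq, light_seq=None, heavy_germ=None,
                light_germ=None, light_v="IGKV1-1*01", light_j="IGKJ1*01",
                light_junction=9, clone_id="clone1"):
    heavy = make_rearrangement(
        f"{cell_id}_H", "IGH", heavy_seq, heavy_germ, cell_id, clone_id
    )
    lights = ()
    if light_seq is not None:
        lights = (
            make_rearrangement(
                f"{cell_id}_L", "IGK", light_seq, light_germ, cell_id, clone_id,
                v_call=light_v, j_call=light_j, junction_length=light_junction,
            ),
        )
    return CellBundle(cell_id=cell_id, heavy=heavy, lights=lights)


def make_alignment(tips, germline, heavy_len=None, clone_id="toy_1"):
    """CloneAlignment straight from sequence strings (no collapsing)."""
    length = len(germline)
    heavy_len = length if heavy_len is None else heavy_len
    return CloneAlignment(
        clone_subgroup_id=clone_id,
        tip_sequences=dict(tips),
        germline=germline,
        heavy_interval=(0, heavy_len),
        light_interval=(heavy_len, length),
        collapse_map={k: {k} for k in tips},
        light_present={k: True for k in tips},
    )


@pytest.fixture(scope="session")
def small_clone_alignments():
    """A few small simulated clones pushed through the full prep pipeline."""
    out = []
    for seed in (11, 12, 13):
        sim = simulate_clone(n_tips=5, branch_mean_events=3.0, seed=seed,
                             heavy_length=30, light_length=18)
        out.append(sim.to_clone_alignment(collapse=False))
    return out


@pytest.fixture(scope="session")
def acceptance_clones():
    """The 40-clone x 20-tip study set used by the headline benchmarks (the
    same design size as scripts/acceptance.py)."""
    return [simulate_clone(n_tips=20, seed=9000 + i, clone_id=f"clone{i + 1}")
            for i in range(40)]
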