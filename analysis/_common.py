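"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

import strepnet

SEED = 20231031
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"
RESULTS.mkdir(parents=True, exist_ok=True)


def get_networks():
    """The deterministic three-community fixture, reading saved matrices if present."""
    paths = {k: DATA / f"matrix_{k}.csv" for k in ("A", "B", "C")}
    if all(p.exists() for p in paths.values()):
        mats = {k: strepnet.read_matrix(p, community_id=k) for k, p in paths.items()}
    else:
        mats = strepnet.synthetic_data.simulate_reference_communities(seed=SEED)
    return {k: strepnet.build_network(m) for k, m in mats.items()}
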