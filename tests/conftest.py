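import numpy as np
import pytest

import hotspotter as h


def make_path_cell(cell_id="c1", n=6, step=5.0):
    """A soma plus one unbranched dendrite along +x, nodes `step` µm apart."""
    nodes = [
        h.AnnotationNode(f"{cell_id}-n0", cell_id, 0.0, 0.0, 25.0, 6.0, None, "soma")
    ]
    for i in range(1, n + 1):
        nodes.append(
            h.AnnotationNode(
                f"{cell_id}-n{i}", cell_id, i * step, 0.0, 25.0, 0.4,
                f"{cell_id}-n{i - 1}", "dendrite",
            )
        )
    return h.NeuronReconstruction(cell_id, "RGC_smooth", nodes)


def synapse_at_node(cell, node_idx, sid, kind="conventional", pre_type="amacrine",
                    pre_cell="preA"):
    n = cell.nodes[node_idx]
    return h.SynapseRecord(sid, pre_cell, cell.cell_id, kind, n.x, n.y, n.z, pre_type)


@pytest.fixture(scope="session")
def paired_scene():
    """One synthetic smooth cell with 4 planted hotspots plus 3 parasols."""
    dataset, truth = h.generate_paired_scene(seed=11)
    return dataset, truth


@pytest.fixture(scope="session")
def smooth_ribbon(paired_scene):
    dataset, truth = paired_scene
    smooth_id = next(c for c, r in truth["roles"].items() if r == "smooth")
    ribbon = h.subset_synapses(dataset, smooth_id, kind="ribbon")
    pts = np.array([[s.x, s.y] for s in ribbon])
    return smooth_id, ribbon, pts
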