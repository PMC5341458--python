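"""Shared fixtures: batch stretch settings, generated study populations,
and an independent networkx shortest-path oracle."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from autoroot import (
    StretchBounds,
    analyse_well_images,
    generate_population,
    generate_proxy_population,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Fixed-lighting stretch bounds used for every synthetic batch: background
#: (20 +/- noise) maps to 0, root material (200) saturates to 255.
BATCH_STRETCH = StretchBounds(40, 190)


def nx_multi_source_distances(intensities, seed_points, mode="clamped"):
    """Independent oracle: multi-source shortest paths via networkx.

    Builds the 8-connected pixel graph with the package's own edge-weight
    formula but delegates the search to networkx, so the Dijkstra kernel is
    cross-checked against an unrelated implementation.
    """
    import networkx as nx

    from autoroot import edge_weight

    H, W = intensities.shape
    G = nx.Graph()
    G.add_nodes_from((y, x) for y in range(H) for x in range(W))
    for y in range(H):
        for x in range(W):
            for dy, dx in ((0, 1), (1, -1), (1, 0), (1, 1)):
                ny, nx_ = y + dy, x + dx
                if 0 <= ny < H and 0 <= nx_ < W:
                    w = edge_weight(
                        intensities[y, x],
                        intensities[ny, nx_],
                        diagonal=(dy != 0 and dx != 0),
                        mode=mode,
                    )
                    G.add_edge((y, x), (ny, nx_), weight=w)
    lengths = nx.multi_source_dijkstra_path_length(
        G, [(y, x) for x, y in seed_points], weight="weight"
    )
    out = np.full((H, W), np.inf)
    for (y, x), v in lengths.items():
        out[y, x] = v
    return out


@pytest.fixture(scope="session")
def proxy_study():
    """200 wells with true primary lengths uniform in [100, 600] px,
    analysed with the batch-empirical likelihood normalisation."""
    population = generate_proxy_population(200, seed=11)
    records = analyse_well_images(
        [img for _, img, _ in population], stretch=BATCH_STRETCH
    )
    truths = [truth for _, _, truth in population]
    return truths, records


@pytest.fixture(scope="session")
def condition_study():
    """Control vs growth-inhibited populations (n=100 each), analysed as
    one batch so both share the empirical normalisation constant."""
    control = generate_population(100, "control", seed=5)
    inhibited = generate_population(100, "inhibited", seed=6)
    images = [img for _, img, _ in control] + [img for _, img, _ in inhibited]
    records = analyse_well_images(images, stretch=BATCH_STRETCH)
    labels = np.array([0] * len(control) + [1] * len(inhibited))
    return records, labels
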