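import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import chronomorph as cm

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One synthetic felid-like study system shared across tests."""
    cfg = cm.SimConfig(seed=42)
    tree, cal, traits, table = cm.simulate_study(cfg)
    return dict(cfg=cfg, tree=tree, cal=cal, traits=traits, table=table)


@pytest.fixture(scope="session")
def scaled_tree(study):
    return cm.time_scale(study["tree"], study["cal"], mode="main",
                         extend_extant=True)


@pytest.fixture(scope="session")
def morphospace(study):
    trans = cm.mosimann_transform(study["table"])
    ordination = cm.pca_morphospace(trans)
    centroids = cm.species_centroids(ordination)
    return dict(transformed=trans, ordination=ordination, centroids=centroids)


def random_binary_tree(rng: np.random.Generator, n_tips: int,
                       min_len: float = 0.1, max_len: float = 2.0) -> cm.TimeTree:
    """Random rooted binary topology with uniform branch lengths, dated."""
    from chronomorph.tree import TimeTree, TreeNode

    nodes = [TreeNode(f"t{i + 1}") for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = TimeTree(nodes[0])
    tree.assign_ages_from_lengths()
    return tree
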