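import numpy as np
import pytest

from cophylo import Tanglegram, Tree, simulate_tanglegram


def make_congruent(host: Tree) -> Tanglegram:
    """A parasite tree identical to the host with an identity tip map."""
    parasite = Tree({v: host.children[v] for v in host.internal}, root=host.root)
    return Tanglegram(
        host=host, parasite=parasite, tip_mapping={t: t for t in host.tips}
    )


def tiny_histories(base_seed: int, count: int, max_parasite_tips: int = 6, **kwargs):
    """Yield ``count`` small simulated histories with mixed event types."""
    defaults = dict(p_cosp=0.75, p_loss=0.25, p_dup=0.08, p_switch=0.12)
    defaults.update(kwargs)
    produced = 0
    seed = 0
    while produced < count:
        seed += 1
        rng = np.random.default_rng(base_seed + seed)
        n_tips = int(rng.integers(3, 6))
        try:
            hist = simulate_tanglegram(n_tips, rng, **defaults)
        except RuntimeError:
            continue
        if hist.tanglegram.parasite.n_tips > max_parasite_tips:
            continue
        produced += 1
        yield hist, rng


@pytest.fixture
def rng():
    return np.random.default_rng(0)
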