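import numpy as np
import pytest

from contourfill import ModelConfig, generate_stimulus, run_model
from contourfill.stimuli import STIMULUS_NAMES


@pytest.fixture(scope="session")
def default_config() -> ModelConfig:
    return ModelConfig()


class _OutputCache:
    """Run the model at most once per stimulus for the whole session."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self._cases = {}
        self._outputs = {}

    def case(self, name: str):
        if name not in self._cases:
            self._cases[name] = generate_stimulus(name)
        return self._cases[name]

    def outputs(self, name: str):
        if name not in self._outputs:
            self._outputs[name] = run_model(self.case(name).image.grid, self.config)
        return self._outputs[name]


@pytest.fixture(scope="session")
def model_cache(default_config) -> _OutputCache:
    return _OutputCache(default_config)


@pytest.fixture(scope="session")
def all_stimulus_names():
    return list(STIMULUS_NAMES)


def region_max_oracle(feature, support, mask_h, mask_v):
    """Brute-force flood-fill oracle for the filling-in steady state.

    Pure-python BFS: supported nodes take the maximum feature over their
    connected component (components via 4-neighbour links not cut by the
    boundary gate, restricted to supported nodes); unsupported nodes keep
    their own feature.
    """
    h, w = feature.shape
    out = feature.astype(float).copy()
    seen = np.zeros((h, w), dtype=bool)

    def neighbours(y, x):
        if y > 0 and not (mask_h[y, x] or mask_h[y - 1, x]):
            yield y - 1, x
        if y < h - 1 and not (mask_h[y, x] or mask_h[y + 1, x]):
            yield y + 1, x
        if x > 0 and not (mask_v[y, x] or mask_v[y, x - 1]):
            yield y, x - 1
        if x < w - 1 and not (mask_v[y, x] or mask_v[y, x + 1]):
            yield y, x + 1

    for sy in range(h):
        for sx in range(w):
            if seen[sy, sx] or not support[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            members = []
            best = -np.inf
            while stack:
                y, x = stack.pop()
                members.append((y, x))
                best = max(best, feature[y, x])
                for ny, nx in neighbours(y, x):
                    if support[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            for y, x in members:
                out[y, x] = best
    return out


def component_max_oracle(ff, pairs, support):
    """Brute-force oracle for the MAX-circuit fixed point on a generic graph."""
    n = len(ff)
    adj = [[] for _ in range(n)]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)
    out = np.array(ff, dtype=float)
    seen = [False] * n
    for s in range(n):
        if seen[s] or not support[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in adj[v]:
                if support[u] and not seen[u]:
                    seen[u] = True
                    stack.append(u)
        best = max(ff[v] for v in comp)
        for v in comp:
            out[v] = best
    return out
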