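"""High-level simulation driver tying lattice, events, and geometry together."""

from __future__ import annotations

import numpy as np

from . import engine
from .dynamics import DynamicsEngine
from .geometry import TissueBlueprint, init_tissue
from .morphology import Snapshot
from .params import SimulationParams


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Deterministic, distinct per-replicate seed below 2**31."""
    return int(np.random.SeedSequence([int(base_seed), int(replicate)])
               .generate_state(1)[0] % (2 ** 31))


class Simulation:
    """One seeded run of the duct model.

    The kernel RNG (pixel copies) and the event RNG (cell choices, division
    angles, death draws) are both derived from ``params.seed``, so an
    identical parameter set reproduces the trajectory bit for bit.
    """

    def __init__(self, params: SimulationParams, archetype: str = "circle",
                 blueprint: TissueBlueprint | None = None):
        params.validate()
        self.params = params
        self.state, self.geometry = init_tissue(params, blueprint, archetype)
        from ._kernel import make_rng_state
        self.kernel_rng = make_rng_state(int(params.seed) % (2 ** 31))
        self.rng = np.random.default_rng([int(params.seed), 1])
        self.dynamics = DynamicsEngine(self.state, params, self.geometry, self.rng)
        engine.rebuild_links(self.state, params)
        self.mcs = 0

    def run(self, n_mcs: int, checkpoint_every: int | None = None,
            on_checkpoint=None) -> None:
        """Advance ``n_mcs`` steps; optionally call ``on_checkpoint(snapshot)``
        every ``checkpoint_every`` MCS."""
        if checkpoint_every is None:
            engine.run_mcs(self.state, self.params, n_mcs,
                           hooks=[self.dynamics.hook], mcs_offset=self.mcs,
                           rng_state=self.kernel_rng)
            self.mcs += n_mcs
            return
        remaining = n_mcs
        while remaining > 0:
            step = min(checkpoint_every - self.mcs % checkpoint_every or
                       checkpoint_every, remaining)
            engine.run_mcs(self.state, self.params, step,
                           hooks=[self.dynamics.hook], mcs_offset=self.mcs,
                           rng_state=self.kernel_rng)
            self.mcs += step
            remaining -= step
            if self.mcs % checkpoint_every == 0 and on_checkpoint is not None:
                on_checkpoint(self.snapshot())

    def snapshot(self) -> Snapshot:
        return Snapshot.from_state(self.state, self.geometry, self.mcs)

    @property
    def event_log(self):
        return self.dynamics.event_log
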