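"""Snapshot serialization, PNG rendering, and YAML run configuration."""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import yaml

from .geometry import Geometry, TissueBlueprint
from .morphology import Snapshot
from .params import LEP, MEP, NECROTIC, AdhesionMatrix, FppParams, SimulationParams

# rendering palette: medium white, LEP green, MEP blue, necrotic red
PALETTE = np.array([
    [255, 255, 255],  # medium
    [60, 170, 60],    # LEP
    [60, 90, 200],    # MEP
    [200, 50, 50],    # necrotic
], dtype=np.uint8)


def render(snapshot: Snapshot, path=None):
    """Render a snapshot to an RGB array (and optionally a PNG file)."""
    rgb = PALETTE[snapshot.typ[snapshot.sites]]
    # darken cell boundaries so individual agents are visible
    s = snapshot.sites
    edge = np.zeros(s.shape, dtype=bool)
    edge[:, :-1] |= s[:, :-1] != s[:, 1:]
    edge[:-1, :] |= s[:-1, :] != s[1:, :]
    edge &= s > 0
    rgb = rgb.copy()
    rgb[edge] = (rgb[edge] * 0.6).astype(np.uint8)
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        plt.imsave(path, rgb)
    return rgb


def save_snapshot(path, snapshot: Snapshot) -> None:
    """Write the lattice and the agent table to a portable ``.npz``."""
    geom = snapshot.geometry
    np.savez_compressed(
        path, mcs=snapshot.mcs, sites=snapshot.sites, typ=snapshot.typ,
        vol=snapshot.vol, coms=snapshot.coms,
        region_mask=geom.region_mask,
        initial_footprint=geom.initial_footprint,
        initial_interior=geom.initial_interior,
        skeleton=geom.skeleton, lumen_radius=geom.lumen_radius,
        lumen_centroid=np.asarray(geom.lumen_centroid), tips=geom.tips,
        archetype=np.bytes_(geom.blueprint.archetype.encode()))


def load_snapshot(path) -> Snapshot:
    z = np.load(path)
    bp = TissueBlueprint(archetype=bytes(z["archetype"]).decode())
    geom = Geometry(blueprint=bp, skeleton=z["skeleton"],
                    lumen_radius=float(z["lumen_radius"]),
                    region_mask=z["region_mask"],
                    initial_footprint=z["initial_footprint"],
                    initial_interior=z["initial_interior"],
                    lumen_centroid=tuple(z["lumen_centroid"]),
                    tips=z["tips"])
    return Snapshot(mcs=int(z["mcs"]), sites=z["sites"], typ=z["typ"],
                    vol=z["vol"], coms=z["coms"], geometry=geom)


def agent_table(snapshot: Snapshot):
    """Sidecar agent table (sigma, type, volume, center of mass)."""
    import pandas as pd

    names = {0: "medium", LEP: "LEP", MEP: "MEP", NECROTIC: "necrotic"}
    idx = np.arange(1, len(snapshot.typ))
    idx = idx[snapshot.vol[idx] > 0]
    return pd.DataFrame(dict(
        sigma=idx, type=[names[int(t)] for t in snapshot.typ[idx]],
        volume=snapshot.vol[idx],
        com_x=snapshot.coms[idx, 0], com_y=snapshot.coms[idx, 1]))


# --------------------------------------------------------------------- config
def params_to_dict(params: SimulationParams) -> dict:
    d = asdict(params)
    d["adhesion"] = asdict(params.adhesion)
    d["fpp"] = asdict(params.fpp)
    return d


def params_from_dict(d: dict) -> SimulationParams:
    d = dict(d)
    adhesion = AdhesionMatrix(**d.pop("adhesion", {}))
    fpp = FppParams(**d.pop("fpp", {}))
    return SimulationParams(adhesion=adhesion, fpp=fpp, **d)


def load_config(path) -> tuple[SimulationParams, dict]:
    """Read a YAML run configuration.

    Top-level keys mirror SimulationParams field names; the optional
    ``geometry`` section selects the archetype and blueprint overrides.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    geometry = raw.pop("geometry", {"archetype": "circle"})
    return params_from_dict(raw), geometry


def save_config(path, params: SimulationParams, geometry: dict | None = None) -> None:
    d = params_to_dict(params)
    if geometry:
        d["geometry"] = geometry
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
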