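"""Decision-boundary maps for the Noise-Integration-Noise observer family.

Reproduces the mechanism dissection: integration over latent causes shifts
the 0.5-choice boundary toward the more complex model; strong sensory noise
shifts it the opposite way; choice noise flattens the map without moving the
boundary. Writes the maps (long format) and the per-mechanism mean boundary
location to results/.
"""

import numpy as np
import pandas as pd

from occam.manifolds import NoiseModel, PointManifold, SegmentManifold
from occam.observers import ObserverConfig, boundary_map

GRID = ((-0.4, 0.4), (0.0, 1.0), 9, 61)


def main() -> None:
    pair = (PointManifold((0.0, 0.0)), SegmentManifold((-0.5, 1.0), (0.5, 1.0)))
    noise = NoiseModel(sigma=1.0, n_obs=1)
    rng = np.random.default_rng(7)
    observers = {
        "no_integration": (ObserverConfig("nin", integration_strength=0.0), 1),
        "integration": (ObserverConfig("nin", integration_strength=1.0), 1),
        "sensory_noise": (
            ObserverConfig("nin", integration_strength=0.0, sensory_noise_rho=1.0),
            1200,
        ),
        "choice_noise": (
            ObserverConfig("nin", integration_strength=0.0, choice_temperature=3.0),
            1200,
        ),
    }
    frames, rows = [], []
    for name, (obs, reps) in observers.items():
        m = boundary_map(obs, pair, GRID, reps, rng, noise)
        gx, gy = np.meshgrid(m["x"], m["y"])
        frames.append(
            pd.DataFrame(
                {"mechanism": name, "x": gx.ravel(), "y": gy.ravel(),
                 "p_complex": m["p2"].ravel()}
            )
        )
        rows.append({"mechanism": name, "mean_boundary_y": np.nanmean(m["boundary_y"])})
        print(f"{name:15s} mean 0.5-boundary at y = {np.nanmean(m['boundary_y']):.3f}")
    pd.concat(frames).to_csv("results/boundary_maps.csv", index=False)
    pd.DataFrame(rows).to_csv("results/boundary_locations.csv", index=False)
    print("\nIntegration raises the boundary toward the complex model; sensory "
          "noise lowers it; choice noise leaves it in place. Maps in results/.")


if __name__ == "__main__":
    main()
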