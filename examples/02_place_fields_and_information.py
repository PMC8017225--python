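"""Place-field maps and the shuffle test for place cells.

Maps one synthetic session with the standard procedure (2 cm bins, end
bins discarded, 8-25 cm/s speed filter, Gaussian smoothing sigma=1.5 bins
over 5 taps), computes each neuron's spatial information content
I = sum_i P_i (lam_i/lam_bar) log2(lam_i/lam_bar), and classifies place
cells against a 1000-sample shuffle null at p < 0.05.
"""

import numpy as np

from placecode import info, maps, synthetic

config = synthetic.SessionConfig(n_neurons=300)
rng = np.random.default_rng(7)
tuning = synthetic.simulate_tuning(config, rng=rng)
session = synthetic.simulate_trajectory(config, rng=rng)
raster = synthetic.simulate_events(session, tuning, rng=rng)

spec = maps.BinningSpec()
speed = maps.compute_speed(session)
pfm = maps.place_field_map(session, raster, spec, "LR", speed=speed)
result = info.score_direction(session, raster, spec, "LR",
                              n_shuffles=1000, seed=7, speed=speed)

pc = result.is_place_cell
print(f"kept spatial bins      {pfm.n_bins} (2 cm each)")
print(f"place cells (LR)       {pc.sum()} / {raster.n_neurons} "
      f"({100 * pc.mean():.1f}%)")
print(f"mean SIC, place cells  {result.sic_bits[pc].mean():.2f} bits")
print(f"high-SIC (>2 bits)     {info.high_sic_count(result.sic_bits[pc])}")
print("\nA place cell carries ~2 bits/event about position: its events")
print("restrict the animal's location to ~a quarter of the track.")
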