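"""Fit 5th-order field dynamics with only 16 probes via compression.

Runs one seed of the headline study: compressed 5th-order fitting with the
16-probe array versus the conventional 3rd-order 16-probe fit and the
100-probe 5th-order reference, scored by degree-0..2 RMSE against the
simulated truth.
"""

from fieldcomp.experiments import headline_experiment

res = headline_experiment(seed=1)
print(f"selected singular values (sweep argmin): L = {res['best_L']}")
print(f"RMSE compressed 5th-order, 16 probes : {res['rmse_compressed_16']:.4f} rad")
print(f"RMSE conventional 3rd-order, 16 probes: {res['rmse_conventional3_16']:.1f} rad")
print(f"RMSE conventional 5th-order, 100 probes: {res['rmse_conventional5_100']:.4f} rad")
ratio = res["rmse_conventional3_16"] / res["rmse_compressed_16"]
print(f"\nThe conventional 16-probe fit cannot represent degrees 4-5, which")
print(f"alias onto the low orders ({ratio:.0f}x larger error here); the")
print("compressed fit reaches near the 100-probe noise floor with 16 probes.")
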