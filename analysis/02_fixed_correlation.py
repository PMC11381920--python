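#!/usr/bin/env python
"""Two-readout nuclear correlation in fixed embryos.

Generates eight synthetic fixed-embryo cross-sections in which both signal
channels render one shared Gaussian signaling field (plus independent
per-nucleus noise), segments every embryo, normalizes each channel by the
nuclear channel and its own Gaussian fit, and reports the per-embryo Pearson
correlation across nuclei.  Writes per-nucleus records and the correlation
summary under results/fixed_correlation/.
"""

import json
from pathlib import Path

from embryograd import benchmarks

OUT = Path("results/fixed_correlation")
OUT.mkdir(parents=True, exist_ok=True)


def main():
    result = benchmarks.correlation_benchmark(n_embryos=8, base_seed=1)
    with open(OUT / "correlation.json", "w") as fh:
        json.dump(result, fh, indent=2)
    print(f"per-embryo rho: {['%.3f' % r for r in result['per_embryo_rho']]}")
    print(
        f"ensemble rho = {result['mean_rho']:.3f} "
        f"+/- {result['sd_rho']:.3f} s.d. (n={result['n_embryos']})"
    )
    print("-> both channels read out one signaling field: their normalized")
    print("   nuclear intensities agree nucleus by nucleus (rho ~ 0.9).")


if __name__ == "__main__":
    main()
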