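#!/usr/bin/env python
"""Generate the synthetic study set and write it to disk.

Produces one live-gradient time course (refining DV Gaussian), one MS2
z-stack time course with planted transcription dots, and one oscillating
control embryo, each as OME-TIFF with a ground-truth JSON sidecar under
scratch/simulated/ (bulky image output stays out of the results tables).
Every downstream driver regenerates what it needs from seeds, so this script
exists to give the reader inspectable images.
"""

from pathlib import Path

from embryograd import io as egio, synth

OUT = Path("scratch/simulated")
OUT.mkdir(parents=True, exist_ok=True)


def save(name, series, gt):
    egio.write_series(series, OUT / f"{name}.ome.tif")
    gt.to_json(OUT / f"{name}.ground_truth.json")
    print(
        f"{name}: {series.n_frames} frames x {series.n_z} z, "
        f"{len(gt.nuclei)} nuclei, {len(gt.dots)} planted dots"
    )


def main():
    live = synth.SyntheticConfig.live_default(n_frames=20, rng_seed=1)
    save("live_gradient", *synth.generate_time_course(live))

    ms2 = synth.SyntheticConfig.ms2_default(n_frames=5, rng_seed=1)
    save("ms2_stack", *synth.generate_ms2_stack(ms2))

    control = synth.SyntheticConfig.live_default(
        n_frames=40, rng_seed=1, image_size=(512, 512), pixel_size=0.30,
        n_nuclei=70, min_component_px=100,
    )
    save("control", *synth.generate_control_embryo(control))


if __name__ == "__main__":
    main()
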