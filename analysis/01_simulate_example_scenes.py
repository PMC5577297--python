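#!/usr/bin/env python
"""Generate one example scene per condition and write them to disk.

Produces, under results/scenes/, a control and a knockdown podocyte scene
(channels as 16-bit TIFFs, ground-truth tables as CSV, spec+seed as JSON),
plus a stretched gradient-fiber scene. These are the inputs the later
analysis steps can be rerun on by hand with the `fcquant` CLI.
"""

import dataclasses

from fcquant.synthetic import (control_spec, generate_gradient_fiber_scene,
                               generate_scene, knockdown_spec, write_scene)

OUT = "results/scenes"
SEED = 42


def main() -> None:
    for name, spec in (("control", control_spec(rng_seed=SEED)),
                       ("knockdown", knockdown_spec(rng_seed=SEED + 1))):
        channels, truth = generate_scene(spec)
        write_scene(channels, truth, f"{OUT}/{name}")
        print(f"{name}: {len(truth.contacts)} true contacts "
              f"-> {OUT}/{name}/")

    gradient = dataclasses.replace(
        control_spec(rng_seed=SEED + 2), morphology_mode="stretched",
        fa_count_law=(0.0, 0.0))
    channels, truth = generate_gradient_fiber_scene(gradient)
    write_scene(channels, truth, f"{OUT}/gradient_fibers")
    print(f"gradient_fibers: {len(truth.fibers)} fibers -> {OUT}/gradient_fibers/")


if __name__ == "__main__":
    main()
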