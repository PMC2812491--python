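"""Generate the toy-network fixtures and pseudo-immunoblot training data.

Writes the expanded irreversible network, the ground-truth parameters,
the hand-tuned start guess, the observation table (six datasets: hormone
time courses for three clones, a growth-factor transient, and +/-50%
perturbation steady states for two clones) and the protocol config.
"""

import argparse
from pathlib import Path

from kinens import workflow


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/workflow")
    args = ap.parse_args()

    res = workflow.generate_fixtures(args.outdir, args.seed)
    bundle, training = res["bundle"], res["training"]
    net = bundle.network
    print(f"toy network: {net.n_species} species, {net.n_reactions} irreversible reactions")
    by_ds = {}
    for o in training.observations:
        by_ds.setdefault(o.dataset_id, []).append(o)
    for did in sorted(by_ds):
        obs = by_ds[did]
        species = sorted({o.species_id for o in obs})
        print(f"  dataset {did:9s}: {len(obs):3d} observations of {species} "
              f"(clone {training.protocols[did].clone})")
    print(f"fixtures written to {Path(args.outdir).resolve()}")


if __name__ == "__main__":
    main()
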