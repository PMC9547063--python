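"""Generate the synthetic cortical microvascular networks used downstream.

Writes node/edge CSV tables plus a provenance record (config + seed +
rheology law version) for two seeded networks under results/networks/.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from capnet.network import assign_branch_orders, save_network
from capnet.synthetic import GeneratorConfig, generate_cortical_mvn, provenance

OUT = Path(__file__).resolve().parents[1] / "results" / "networks"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-networks", type=int, default=2)
    args = parser.parse_args()

    seeds = [int(s) % (2**31 - 1) for s in np.random.SeedSequence(args.seed).generate_state(args.n_networks)]
    for k, seed in enumerate(seeds):
        cfg = GeneratorConfig(seed=seed)
        net = generate_cortical_mvn(cfg)
        assign_branch_orders(net)
        cap = net.vessel_type == "capillary"
        out = OUT / f"net{k}"
        out.mkdir(parents=True, exist_ok=True)
        save_network(net, out / "nodes.csv", out / "edges.csv")
        (out / "provenance.json").write_text(json.dumps(provenance(cfg), indent=2))
        print(
            f"net{k}: seed={seed} vessels={net.n_vessels} "
            f"capillary fraction={cap.mean():.3f} "
            f"capillary diameter={net.diameter[cap].mean():.2f}±{net.diameter[cap].std():.2f} µm "
            f"-> {out}"
        )


if __name__ == "__main__":
    main()
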