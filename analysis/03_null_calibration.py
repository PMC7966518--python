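"""Calibration of the standardized lesion distance under the null.

Pseudo-lesion medians drawn from a subject's own white-matter intensity
distribution should rarely exceed Z = 2.3: the exceedance fraction estimates
the statistic's false-positive rate and should stay below 0.05.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from bhtyper import distance, phantom

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-pseudo", type=int, default=2000)
    parser.add_argument("--n-seeds", type=int, default=10)
    args = parser.parse_args()

    spec = phantom.CohortSpec(
        n_subjects=1, grid_shape=(48, 48, 48), lesion_size_range=(60, 400),
        master_seed=args.seed + 101,
    )
    subject = phantom.generate_subject(spec, 0)
    per_seq = {}
    for seq in phantom.SEQUENCES:
        wm = subject.volumes[seq][
            (subject.tissue_maps["wm"] > 0.5) & (subject.lesion_labels == 0)
        ].astype(np.float64)
        exceed = total = 0
        for k in range(args.n_seeds):
            null = distance.build_null(
                wm, distance.NullConfig(n_samples=5000, rng_seed=args.seed + k)
            )
            rng = np.random.default_rng(args.seed + 10_000 + k)
            pseudo = rng.choice(wm, size=args.n_pseudo, replace=True)
            z = distance.z_scores(pseudo, null)["z"].to_numpy()
            exceed += int((z > 2.3).sum())
            total += args.n_pseudo
        per_seq[seq] = {"exceedance_fraction": exceed / total, "n": total}
        print(f"{seq}: {exceed}/{total} pseudo-lesions above Z = 2.3 "
              f"({100 * exceed / total:.2f}%)")

    out = ROOT / "results" / "null_calibration.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(per_seq, indent=2))
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
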