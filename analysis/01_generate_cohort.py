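"""Generate the synthetic tagging campaign: tracks, 30-s tag records, and
noon-position tables for six staggered deployments, plus a manifest of
every ground-truth parameter.  Raw records are written in the tag text
format under scratch/analysis/."""

import numpy as np

import sealight as sl
from _common import SCRATCH, TRUTH, deployment_specs, ensure_dirs


def main():
    ensure_dirs()
    specs = deployment_specs()
    sl.save_manifest(SCRATCH / "manifest.json", TRUTH, specs)
    total = 0
    for spec in specs:
        track = sl.generate_track(spec, TRUTH)
        deployment = sl.generate_dive_series(spec, track, TRUTH)
        sl.write_tag_file(SCRATCH / f"{spec.seal_id}.csv", deployment)
        track.to_csv(SCRATCH / f"{spec.seal_id}_positions.csv", index=False)
        total += len(deployment)
        print(f"{spec.seal_id}: {spec.n_days} days from {spec.start_date}, "
              f"{len(deployment)} records, "
              f"track {track.lat.min():.1f}..{track.lat.max():.1f} S")
    print(f"\nwrote {total} records for {len(specs)} seals to {SCRATCH}")
    print(f"planted log-log index/chl slope beta_true = {TRUTH.beta_true}")


if __name__ == "__main__":
    main()
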