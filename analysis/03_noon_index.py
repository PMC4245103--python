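"""Compute the daily local-noon LA250 index for every deployment: zero
offset correction, dive segmentation, the 1100-1300 local solar window,
per-dive (LL0 - LL250)/250, daily aggregation, and the T200-based frontal
zone of each seal-day."""

import pandas as pd

import sealight as sl
from _common import RESULTS, SCRATCH, deployment_specs, ensure_dirs


def main():
    ensure_dirs()
    frames = []
    for spec in deployment_specs():
        dep = sl.read_tag_file(SCRATCH / f"{spec.seal_id}.csv")
        positions = pd.read_csv(SCRATCH / f"{spec.seal_id}_positions.csv",
                                parse_dates=["date"])
        positions["date"] = positions["date"].dt.date
        frames.append(sl.process_deployment(dep, positions))
    noon = pd.concat(frames, ignore_index=True)
    noon.to_csv(RESULTS / "noon_index.csv", index=False)

    analysable = noon[noon["analysable"]]
    print(f"{len(noon)} seal-days with noon profiles; "
          f"{len(analysable)} analysable (>= 3 light profiles)")
    print(f"light profiles per seal-day: "
          f"{noon.n_profiles.mean():.1f} +/- {noon.n_profiles.std():.1f}")
    print("\nfrontal-zone occupancy of analysable seal-days:")
    print(analysable["zone"].value_counts().to_string())
    print(f"\nLA250 range {analysable.la250.min():.3f}"
          f"..{analysable.la250.max():.3f} levels/m "
          f"-> {RESULTS}/noon_index.csv")


if __name__ == "__main__":
    main()
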