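"""Zero-offset correct and segment every deployment; summarize the dive
record and the depth of the mixed layer and of the bulk of phytoplankton
(temperature and light broken-stick inflections), including the fraction
of dives whose inflections sit above 250 m -- the justification for
integrating attenuation over the top 250 m."""

import numpy as np
import pandas as pd

import sealight as sl
from sealight import dives as dv, hydrography as hyd
from _common import RESULTS, SCRATCH, deployment_specs, ensure_dirs


def main():
    ensure_dirs()
    rows, inflections = [], []
    for spec in deployment_specs():
        dep = sl.read_tag_file(SCRATCH / f"{spec.seal_id}.csv")
        depth = sl.zero_offset_correct(dep.depth)
        seg = sl.segment_dives(depth, dep.time)
        assert seg.conserved
        for dive in seg.dives:
            try:
                desc, asc = dv.split_phases(dive)
            except ValueError:
                continue
            mld = hyd.mixed_layer_depth(depth[desc], dep.temperature[desc],
                                        criterion="across_breakpoint")
            light = hyd.light_inflection_depth(
                depth[desc], dep.light_level[desc],
                depth[asc], dep.light_level[asc])
            inflections.append({"seal": spec.seal_id, "mld_m": mld,
                                "light_inflection_m": light})
        rows.append({
            "seal": spec.seal_id,
            "n_dives": len(seg.dives),
            "dives_per_day": len(seg.dives) / spec.n_days,
            "median_max_depth_m": np.median([d.max_depth for d in seg.dives]),
            "n_incomplete_records": seg.n_incomplete_records,
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "dive_summary.csv", index=False)
    print(summary.to_string(index=False))

    infl = pd.DataFrame(inflections)
    frac_mld = (infl.mld_m.dropna() <= 250).mean()
    frac_light = (infl.light_inflection_m.dropna() <= 250).mean()
    infl.describe().to_csv(RESULTS / "inflection_summary.csv")
    print(f"\nmixed layer above 250 m in {100 * frac_mld:.1f}% of dives; "
          f"light inflection above 250 m in {100 * frac_light:.1f}%")
    print(f"tables -> {RESULTS}/dive_summary.csv, inflection_summary.csv")


if __name__ == "__main__":
    main()
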