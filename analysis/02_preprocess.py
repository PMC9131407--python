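"""Apply the exclusion rules and build orientation profiles.

Participants with > 20% errors are excluded; the RT stream keeps correct
responses between 150 and 2000 ms; profiles are per participant x movement x
person-location mean RTs (and error rates) per orientation.  Writes the
retained profiles and the exclusion report under results/preprocessed/.
"""

import json
from pathlib import Path

import pandas as pd

from vptlab.preprocess import exclude_participants, filter_trials, orientation_profiles

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    trials = pd.read_csv(ROOT / "cohort" / "trials.csv")
    retained, report = exclude_participants(trials)
    kept = trials[trials.participant_id.isin(retained)]
    filt = filter_trials(kept)

    out = ROOT / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "exclusion_report.csv", index=False)
    (out / "filter_log.json").write_text(json.dumps(filt.log, indent=2))
    orientation_profiles(filt.rt_stream, "rt_ms").to_csv(out / "profiles_rt.csv", index=False)
    orientation_profiles(filt.error_stream, "error_rate").to_csv(
        out / "profiles_error.csv", index=False)

    print(f"retained {len(retained)} of {trials.participant_id.nunique()} participants")
    print(f"RT stream kept {filt.log['n_retained_rt']} of {filt.log['n_input']} trials "
          f"({filt.log['n_error']} errors, {filt.log['n_too_slow']} > 2000 ms, "
          f"{filt.log['n_too_fast']} < 150 ms removed)")
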