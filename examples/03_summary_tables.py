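"""Reproduce the study-style summary shares from the bundled example tables.

The package ships the aggregated two-year monitoring tables for the
Sebastian, FL array; the summary operations recompute every reported
proportion from the raw counts.
"""

from rayvisits import group_share_percent, proportion_visit_time
from rayvisits import example_tables as ex

counts = ex.detection_counts()
print("eagle-ray share of detections at SINJ:",
      group_share_percent(counts, ["SINJ"], "A_narinari"), "%")
print("pooled cownose share at the clam leases:",
      group_share_percent(counts, ex.CLAM_LEASE_RECEIVERS,
                          ["R_bonasus", "R_brasiliensis"]), "%")

vs = ex.visit_summary()
print("total visits across species:", int(vs["n_visits"].sum()))
print("eagle-ray total visit time:",
      round(vs.loc[vs['species'] == 'A_narinari', 'total_time_min'].sum(), 1), "min")

shares = proportion_visit_time(vs, ex.REGION)
eagle_inlet = shares.query("species=='A_narinari' and group=='inlet'")["percent"].iloc[0]
print(f"eagle rays spent {eagle_inlet}% of visit time at the inlet receivers")

loc = proportion_visit_time(vs, ex.GENERAL_LOCATION)
cnr_lease = loc.query("species=='R_bonasus' and group=='clam_lease'")["percent"].iloc[0]
print(f"Atlantic cownose rays spent {cnr_lease}% of visit time over the clam leases")
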