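"""Generate a synthetic isotope study and apply the inclusion filters.

Builds a small bundle (individuals, radiocarbon dates, calibration curve,
climate grid), then runs the quality-control rules: under-fives out,
unreliable collagen (C:N outside 2.9-3.6 without author override) out,
Colonial-period individuals out.
"""

from paleodiet import make_bundle, qc_filter
from paleodiet.demography import qc_dates

bundle = make_bundle(seed=42, n_individuals=300, n_dates_per_zone=150)
retained, report = qc_filter(bundle.individuals)
print("individual QC:", report.to_json())

kept_dates, date_report = qc_dates(bundle.dates)
print("date QC:", date_report.to_json())

# The reports tally every rule in application order (age -> C:N -> period),
# so input always equals retained plus the sum of the dropped counts.
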