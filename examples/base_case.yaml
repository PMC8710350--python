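# Base-case run on synthetic inputs: six adjuvant regimens vs no
# chemotherapy for a cohort of 60-year-old patients with resected stage
# III colon cancer.  Risk scenarios ("low_risk": T1-3 N1; "high_risk":
# T4 and/or N2 -- labels only, the model consumes risk-specific
# recurrence inputs) restrict the comparison to the oxaliplatin arms.
schema_version: 1
seed: 0
scenario: base
wtp: 13006.56
output_dir: out
psa:
  n: 1000
dsa:
  - path: hepatectomy_cost
    low: 3000.0
    high: 9000.0
  - path: metastatic.line1_monthly_cost
    low: 400.0
    high: 1200.0
  - path: costs.FOLFOX_6MO.admin_course_total
    low: 0.0
    high: 2416.33
  - path: recurrence_multiplier.CAPOX_3MO
    low: 0.8
    high: 1.2
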