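"""Score one questionnaire response and derive the severity band tables.

Builds a single 25-item response, computes the conventional total score and
label, then prints the per-group severity ranges that feature group
partitioning derives from the shipped constants.
"""
import bdcfgp as b

# a respondent with moderate thought/feeling symptoms, few physical symptoms
weights = [2] * 10 + [1] * 7 + [0] * 5 + [1] * 3
total = b.cds_score(weights)
label = b.cds_severity(total)
print(f"total score {total} -> {label.label}")
# 30 of 100 falls in the 26-50 band: moderate depression

scores = b.compute_individual_scores(weights)
print("group scores (TFG, APR, PSG, SUG):", scores.as_tuple())
print("prediction target score:", b.compute_pts(scores))
# group scores sum to the conventional total by construction

record = b.fgp_record(weights)
print("group targets:", record.tfg_it.label, "/", record.apr_it.label,
      "/", record.psg_it.label, "/", record.sug_it.label)
print("prediction target:", record.pt.label)

print("\nderived severity ranges (rows: severity, columns: group):")
print(b.range_report().to_string(index=False))
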