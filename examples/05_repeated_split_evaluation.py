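"""Repeated stratified train/test evaluation of three score models.

Each of R random 2/3-1/3 splits refits FPCA and the logistic model on the
training curves only, then scores the held-out subjects.  The three rows
compare thermogram scores, first-derivative ("velocity") scores, and both.
"""

from thermofda import SimConfig, compare_models, generate_cohort, restrict_window

cohort = generate_cohort(SimConfig(seed=51))
window = restrict_window(cohort, 60.0, 85.0)

table = compare_models(window, R=50, seed=51)
cols = ["model", "accuracy", "sensitivity", "specificity", "raoa_accuracy"]
print(table[cols].to_string(index=False,
                            float_format=lambda v: f"{100 * v:6.2f}%"))
# Accuracy is the held-out correct-classification rate averaged over splits
# (sensitivity: cases called cases; specificity: controls called controls).
# The RA/OA column is the rate at which arthritis-positive, lupus-negative
# controls are correctly kept out of the lupus class - a specificity check
# against a confusable disease.
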