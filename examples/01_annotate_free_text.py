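"""Annotate free-text medication and comorbidity histories.

Runs the two-level string matcher (exact, then Damerau-Levenshtein at
similarity >= 0.85) with negation handling on a few realistic snippets
and prints which drug classes and conditions were linked.
"""

from gaitmod import (
    annotate_conditions,
    annotate_medications,
    default_condition_lexicon,
    default_drug_lexicon,
)

drug_lexicon = default_drug_lexicon()
condition_lexicon = default_condition_lexicon()

med_texts = [
    "Atorvastatin 40mg, Aspirin cardio, Bisoprolol 5mg",
    "Metformine 500, patient does not take aspirin",  # typo + negation
    "Lipitor 20mg, kein Insulin",  # brand name + German negation
]
for text in med_texts:
    report = annotate_medications(text, drug_lexicon)
    print(f"{text!r}")
    print(
        f"  -> classes {sorted(report.codes)} "
        f"(exact {report.n_exact}, approximate {report.n_approximate}, "
        f"negated {report.n_negated})"
    )

history = "bekannter Bluthochdruck, coronary hart disease seit 2015"
report = annotate_conditions(history, condition_lexicon)
print(f"\n{history!r}\n  -> conditions {sorted(report.codes)}")

# The matcher accepts 'Metformine' (one edit from metformin, similarity
# 0.90) and 'hart' inside the moving window for 'coronary heart disease',
# but discards the negated aspirin and insulin mentions entirely.
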