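"""Nottingham component scores -> final grade -> binary label.

Each component (nuclear pleomorphism, tubule formation, mitotic count)
scores 1-3; the sum maps to grade 1 (3-5), 2 (6-7) or 3 (8-9), and the
binary task is low/intermediate (grades 1-2) versus high (grade 3).
"""

from milgrade.grading import ComponentScores, binarize_grade, grade_from_components

for triple in [(1, 2, 2), (2, 2, 3), (3, 3, 2), (3, 3, 3)]:
    scores = ComponentScores(*triple)
    grade = grade_from_components(scores)
    print(
        f"nuclear={scores.nuclear} tubular={scores.tubular} "
        f"mitotic={scores.mitotic}  sum={scores.total}  "
        f"grade={grade}  binary={binarize_grade(grade)}"
    )
# The binary column is what the MIL model is trained to predict from the
# whole-slide image alone.
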