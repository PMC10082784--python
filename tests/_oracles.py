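"""Literal brute-force transcriptions of the labeling and strategy rules.

These oracles are deliberately written as plain per-image Python loops with
no shared code paths with the package, so that the vectorized
implementations can be checked against an independent reading of the rules.
"""


def consensus_label_oracle(ratings):
    """Majority vote of binarized reads; ties fall to the mean-rating rule."""
    pos = sum(1 for r in ratings if r >= 4.5)
    neg = len(ratings) - pos
    if pos > neg:
        return 1
    if neg > pos:
        return 0
    return 1 if sum(ratings) / len(ratings) >= 4.5 else 0


def difficult_oracle(ratings, label):
    """At least two panel reads disagree with the consensus label."""
    disagree = sum(1 for r in ratings if (1 if r >= 4.5 else 0) != label)
    return disagree >= 2


def ai_rating_oracle(p):
    return 1 + 7 * p


def ai_aided_physician_oracle(rating, p):
    """Physician first; defer to the AI when the rating is 4 or 5."""
    if rating in (4, 5):
        score = ai_rating_oracle(p)
    else:
        score = rating
    return score, 1 if score >= 4.5 else 0


def physician_aided_ai_oracle(rating, p):
    """AI first; defer to the physician when the AI score is in [3.5, 5.5)."""
    ai_score = ai_rating_oracle(p)
    if 3.5 <= ai_score < 5.5:
        score = rating
    else:
        score = ai_score
    return score, 1 if score >= 4.5 else 0


def average_oracle(rating, p):
    score = (rating + ai_rating_oracle(p)) / 2
    return score, 1 if score >= 4.5 else 0


def weighted_oracle(rating, p, w):
    score = w * rating + (1 - w) * ai_rating_oracle(p)
    return score, 1 if score >= 4.5 else 0


def audit_route_oracle(rating, p):
    """True when physician and AI binary calls disagree (second read needed)."""
    return (rating >= 4.5) != (ai_rating_oracle(p) >= 4.5)


def confusion_oracle(decisions, labels):
    """Tally-by-loop confusion counts."""
    tp = fp = fn = tn = 0
    for d, y in zip(decisions, labels):
        if d and y:
            tp += 1
        elif d and not y:
            fp += 1
        elif not d and y:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn
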