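"""Independent brute-force oracles.

Deliberately re-implemented from scratch with plain loops and their own
hard-coded code prefixes — no helpers shared with the package — so that
agreement with the pipeline is a genuine two-route check.
"""

from __future__ import annotations

# hard-coded prefix sets (dot-stripped, uppercased), duplicated on purpose
_EPILEPSY = {("icd9", "345"), ("icd10", "G40")}
_SEIZURE_RELATED = {("icd9", "345"), ("icd10", "G40"),
                    ("icd9", "7803"), ("icd10", "R56")}
_SE = {("icd9", "3453"), ("icd10", "G40901"), ("icd10", "G40911"),
       ("icd10", "G40401"), ("icd10", "G40411")}
_DIAG_PROC = {"95819", "95816", "70551", "70450"}
_EP_PROC = {"957", "61533"}
_ASM_NAMES = {
    "levetiracetam", "oxcarbazepine", "lamotrigine", "valproate",
    "topiramate", "ethosuximide", "phenobarbital", "carbamazepine",
    "zonisamide", "clobazam", "lacosamide", "perampanel", "gabapentin",
}


def _norm(code: str) -> str:
    return code.replace(".", "").upper()


def _in(pairs, code) -> bool:
    n = _norm(code.code)
    for dialect, prefix in pairs:
        if code.dialect == dialect and n.startswith(prefix):
            return True
    return False


def _is_ep(code) -> bool:
    return _in(_EPILEPSY, code)


def _is_seiz(code) -> bool:
    return _in(_SEIZURE_RELATED, code)


def oracle_outcome(patient, index_date: int) -> dict:
    """All eight outcome booleans, default thresholds, by direct enumeration."""
    lo = index_date + 7
    hi = index_date + 730

    def in_win(d):
        return lo < d <= hi

    win_encs = [e for e in patient.encounters if in_win(e.date)]

    # status epilepticus
    se = False
    for e in win_encs:
        billing = [e.primary_code] + (
            [e.admitting_code] if e.admitting_code is not None else [])
        has_se_positions = [i for i in range(len(e.codes))
                            if _in(_SE, e.codes[i])]
        if not has_se_positions:
            continue
        if any(i in billing for i in has_se_positions):
            se = True
        elif any(_is_ep(e.codes[i]) for i in billing):
            se = True

    # procedures
    proc = False
    for p in patient.procedures:
        if not in_win(p.date):
            continue
        npz = _norm(p.code)
        if p.dialect != "cpt" or not any(npz.startswith(x) for x in _EP_PROC):
            continue
        ok_anchor = False
        for e in patient.encounters:
            if e.date != p.date:
                continue
            billing = [e.primary_code] + (
                [e.admitting_code] if e.admitting_code is not None else [])
            if any(_is_ep(e.codes[i]) for i in billing):
                ok_anchor = True
        if not ok_anchor:
            continue
        for e in patient.encounters:
            if e.date >= p.date + 7 and any(_is_ep(c) for c in e.codes):
                proc = True

    # ASM co-occurrence
    ep_days = set()
    for e in patient.encounters:
        if any(_is_ep(c) for c in e.codes):
            ep_days.add(e.date)
    asm = False
    for m in patient.medications:
        if in_win(m.date) and m.drug.lower() in _ASM_NAMES \
                and m.date in ep_days:
            asm = True

    # utilisation
    seiz_days = {e.date for e in win_encs
                 if any(_is_seiz(c) for c in e.codes)}
    all_days = {e.date for e in win_encs}
    seiz_util = len(seiz_days) >= 2
    all_util = len(all_days) >= 4

    # inpatient admissions for seizures
    n_inp = 0
    for e in win_encs:
        if e.setting == "inpatient" and any(_is_seiz(c) for c in e.codes):
            n_inp += 1
    inpatient = n_inp >= 1

    # diagnostics
    all_seiz_days = {e.date for e in patient.encounters
                     if any(_is_seiz(c) for c in e.codes)}
    n_diag = 0
    for p in patient.procedures:
        if in_win(p.date) and p.dialect == "cpt" \
                and any(_norm(p.code).startswith(x) for x in _DIAG_PROC) \
                and p.date in all_seiz_days:
            n_diag += 1
    diagnostics = n_diag >= 1

    fields = {
        "asm": asm, "status_epilepticus": se, "inpatient_seizure": inpatient,
        "seizure_utilisation": seiz_util, "all_utilisation": all_util,
        "diagnostics": diagnostics, "procedure": proc,
    }
    fields["composite"] = (asm or se or inpatient or seiz_util or all_util
                           or diagnostics or proc)
    return fields


_SEIZURE_LIKE = {("icd9", "345"), ("icd10", "G40"),
                 ("icd9", "7803"), ("icd10", "R56")}


def oracle_inclusion(patient, modality: str = "emr"):
    """(included, reason) from a straightforward re-reading of the rules."""
    index_enc = None
    for e in sorted(patient.encounters, key=lambda e: e.date):
        if any(_in(_SEIZURE_LIKE, c) for c in e.codes):
            index_enc = e
            break
    if index_enc is None:
        return False, "no_index_event"
    age = index_enc.date - patient.birth_date
    if age >= 21 * 365:
        return False, "no_index_event"
    infant = age < 365
    need = 7 if infant else 365
    if modality == "emr":
        prior = False
        for e in patient.encounters:
            if e.date > index_enc.date - need:
                continue
            if infant and any(_in(_SEIZURE_LIKE, c) for c in e.codes):
                continue
            prior = True
        follow = any(e.date >= index_enc.date + 730
                     for e in patient.encounters)
    else:
        target = index_enc.date - need
        prior = any(c.start <= target <= c.end for c in patient.coverage)
        follow = any(c.end >= index_enc.date + 730 for c in patient.coverage)
    if not prior:
        return False, "prior_contact"
    if not follow:
        return False, "followup"
    return True, None


def oracle_auroc(labels, scores) -> float:
    """Pairwise enumeration with 0.5 credit for ties."""
    pos = [s for y, s in zip(labels, scores) if y]
    neg = [s for y, s in zip(labels, scores) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_f1(labels, scores, threshold=0.5) -> float:
    tp = sum(1 for y, s in zip(labels, scores) if y and s >= threshold)
    fp = sum(1 for y, s in zip(labels, scores) if not y and s >= threshold)
    fn = sum(1 for y, s in zip(labels, scores) if y and s < threshold)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def oracle_margin_pick(scores, threshold=0.5):
    """(class, margin) by explicit scan replicating the declared tie rule:
    largest |score - threshold| wins; among equal margins prefer the
    positive side, then the earliest prediction."""
    best = None  # (margin, is_pos, index, score)
    for i, s in enumerate(scores):
        m = abs(s - threshold)
        is_pos = s >= threshold
        if best is None:
            best = (m, is_pos, i, s)
            continue
        bm, bpos, bi, bs = best
        if m > bm or (m == bm and is_pos and not bpos):
            best = (m, is_pos, i, s)
    m, is_pos, i, s = best
    return int(is_pos), m, i
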