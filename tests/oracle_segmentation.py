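"""Brute-force reference segmenter: label every sample, then scan streaks.

Kept deliberately independent of the production implementation (plain
Python loops, no shared helpers) so it can serve as an oracle on small
trajectories.
"""

import math

FIX, SAC, GAP, UNK = "fix", "sac", "gap", "unk"


def brute_force_segment(traj, threshold_mm_s, geometry,
                        limits=(5.8, 6.4)):
    """Return (fixation index tuples, saccade descriptors) per the event
    model: slow streaks (split at the dispersion limits), fast streaks,
    gaps breaking both."""
    n = len(traj.t)
    x = [traj.x_pct[i] / 100.0 * geometry.width_px for i in range(n)]
    y = [traj.y_pct[i] / 100.0 * geometry.height_px for i in range(n)]

    speeds = [None] * n  # attributed to the later sample
    for i in range(1, n):
        if traj.touching[i] and traj.touching[i - 1]:
            d = math.hypot(x[i] - x[i - 1], y[i] - y[i - 1])
            dt = (traj.t[i] - traj.t[i - 1]) / 1000.0
            speeds[i] = d * geometry.pixel_pitch / dt

    labels = []
    for i in range(n):
        if not traj.touching[i]:
            labels.append(GAP)
        elif speeds[i] is None:
            labels.append(UNK)
        elif speeds[i] > threshold_mm_s:
            labels.append(SAC)
        else:
            labels.append(FIX)
    # unknowns adopt the nearest following fix/sac, else nearest preceding,
    # else fix
    for i in range(n):
        if labels[i] != UNK:
            continue
        resolved = None
        for j in range(i + 1, n):
            if labels[j] in (FIX, SAC):
                resolved = labels[j]
                break
        if resolved is None:
            for j in range(i - 1, -1, -1):
                if labels[j] in (FIX, SAC):
                    resolved = labels[j]
                    break
        labels[i] = resolved if resolved is not None else FIX

    # streak scan
    events = []  # (kind, [indices])
    i = 0
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        if labels[i] == FIX:
            # greedy dispersion split
            k = i
            while k <= j:
                members = [k]
                m = k + 1
                while m <= j:
                    cand = members + [m]
                    xs = [x[c] for c in cand]
                    ys = [y[c] for c in cand]
                    if (max(xs) - min(xs) >= limits[0]
                            or max(ys) - min(ys) >= limits[1]):
                        break
                    members.append(m)
                    m += 1
                events.append((FIX, members))
                k = members[-1] + 1
        elif labels[i] == SAC:
            events.append((SAC, list(range(i, j + 1))))
        i = j + 1

    fixations = []
    for kind, members in events:
        if kind == FIX:
            fixations.append({
                "indices": tuple(members),
                "bary_x": sum(x[m] for m in members) / len(members),
                "bary_y": sum(y[m] for m in members) / len(members),
                "start_t": traj.t[members[0]], "end_t": traj.t[members[-1]]})
    saccades = []
    fix_ptr = -1
    for pos, (kind, members) in enumerate(events):
        if kind == FIX:
            fix_ptr += 1
            continue
        prev_fix = next_fix = None
        if pos > 0 and events[pos - 1][0] == FIX \
                and events[pos - 1][1][-1] == members[0] - 1:
            prev_fix = fix_ptr
        if pos + 1 < len(events) and events[pos + 1][0] == FIX \
                and events[pos + 1][1][0] == members[-1] + 1:
            next_fix = fix_ptr + 1
        if prev_fix is not None and next_fix is not None:
            a, b = fixations[prev_fix], fixations[next_fix]
            length = math.hypot(b["bary_x"] - a["bary_x"],
                                b["bary_y"] - a["bary_y"]) * geometry.pixel_pitch
        else:
            length = float("nan")
        member_speeds = [speeds[m] for m in members if speeds[m] is not None]
        mean_speed = (sum(member_speeds) / len(member_speeds)
                      if member_speeds else float("nan"))
        direction = ("progressive" if x[members[-1]] > x[members[0]]
                     else "regressive")
        saccades.append({"indices": tuple(members), "from": prev_fix,
                         "to": next_fix, "length": length,
                         "mean_speed": mean_speed, "direction": direction})
    return fixations, saccades
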