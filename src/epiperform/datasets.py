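"""Bundled example data: published clock-age estimates for a small cohort.

A 21-subject community-dwelling adult cohort (ages 39–70) with
chronological age and biological-age estimates from four epigenetic
clocks (DNAmAge, DNAmAgeHannum, DNAmPhenoAge, DNAmAgeSkinBloodClock),
as printed — i.e. rounded to whole years.  Used for worked examples and
for exercising the tertile and delta machinery on real clock output.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["example_clock_ages", "CLOCK_COLUMNS"]

CLOCK_COLUMNS = ("DNAmAge", "DNAmAgeHannum", "DNAmPhenoAge",
                 "DNAmAgeSkinBloodClock")

_TABLE = """\
subject\tchronological_age\tDNAmAge\tDNAmAgeHannum\tDNAmPhenoAge\tDNAmAgeSkinBloodClock
C2-1\t69\t61\t32\t54\t56
C2-2\t55\t46\t39\t34\t55
C2-3\t59\t38\t51\t36\t66
C2-4\t55\t48\t33\t39\t54
C2-7\t69\t85\t53\t64\t73
C2-8\t55\t45\t37\t42\t46
C2-9\t59\t56\t53\t50\t60
C2-10\t55\t71\t51\t50\t63
C2-11\t50\t56\t33\t39\t53
C2-12\t57\t55\t42\t47\t54
C2-13\t64\t83\t46\t96\t52
C2-14\t67\t67\t45\t47\t65
C2-15\t70\t82\t54\t63\t67
C2-16\t50\t46\t30\t37\t46
C2-18\t58\t59\t37\t43\t56
C2-19\t59\t64\t42\t44\t55
C2-20\t39\t42\t21\t29\t35
C2-21\t51\t57\t36\t48\t51
C2-22\t65\t67\t42\t51\t60
C2-23\t43\t60\t36\t45\t50
C2-24\t51\t48\t33\t42\t45
"""


def example_clock_ages() -> pd.DataFrame:
    """Return the example cohort's clock ages, indexed by subject id."""
    return pd.read_csv(io.StringIO(_TABLE), sep="\t", index_col="subject")
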