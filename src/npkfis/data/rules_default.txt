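# Fuzzy fertilizer-recommendation rules.
# Levels: inputs L/A/H/E; outputs L/M/H, NIL = no contribution.
IF N is L AND P is L AND K is L THEN R.N is H AND R.P is H AND R.K is H AND S.F is L
IF N is L AND P is L AND K is A THEN R.N is H AND R.P is H AND R.K is M AND S.F is L
IF N is L AND P is L AND K is H THEN R.N is H AND R.P is H AND R.K is L AND S.F is L
IF N is L AND P is L AND K is E THEN R.N is H AND R.P is H AND R.K is L AND S.F is L
IF N is L AND P is A AND K is L THEN R.N is H AND R.P is M AND R.K is H AND S.F is L
IF N is L AND P is A AND K is A THEN R.N is H AND R.P is M AND R.K is M AND S.F is L
IF N is L AND P is A AND K is H THEN R.N is H AND R.P is M AND R.K is L AND S.F is L
IF N is L AND P is A AND K is E THEN R.N is H AND R.P is M AND R.K is L AND S.F is L
IF N is L AND P is H AND K is L THEN R.N is H AND R.P is L AND R.K is H AND S.F is L
IF N is L AND P is H AND K is A THEN R.N is H AND R.P is L AND R.K is M AND S.F is L
IF N is L AND P is H AND K is H THEN R.N is H AND R.P is L AND R.K is L AND S.F is L
IF N is L AND P is H AND K is E THEN R.N is H AND R.P is L AND R.K is L AND S.F is L
IF N is L AND P is E AND K is L THEN R.N is H AND R.P is NIL AND R.K is H AND S.F is L
IF N is L AND P is E AND K is A THEN R.N is H AND R.P is NIL AND R.K is M AND S.F is L
IF N is L AND P is E AND K is H THEN R.N is H AND R.P is NIL AND R.K is L AND S.F is L
IF N is L AND P is E AND K is E THEN R.N is H AND R.P is NIL AND R.K is L AND S.F is L
IF N is A AND P is L AND K is L THEN R.N is M AND R.P is H AND R.K is H AND S.F is L
IF N is A AND P is L AND K is A THEN R.N is M AND R.P is H AND R.K is M AND S.F is L
IF N is A AND P is L AND K is H THEN R.N is M AND R.P is H AND R.K is L AND S.F is L
IF N is A AND P is L AND K is E THEN R.N is M AND R.P is H AND R.K is L AND S.F is L
IF N is A AND P is A AND K is L THEN R.N is M AND R.P is M AND R.K is H AND S.F is L
IF N is A AND P is A AND K is A THEN R.N is M AND R.P is M AND R.K is M AND S.F is H
IF N is A AND P is A AND K is H THEN R.N is M AND R.P is M AND R.K is L AND S.F is H
IF N is A AND P is A AND K is E THEN R.N is M AND R.P is M AND R.K is L AND S.F is M
IF N is A AND P is H AND K is L THEN R.N is M AND R.P is L AND R.K is H AND S.F is L
IF N is A AND P is H AND K is A THEN R.N is M AND R.P is L AND R.K is M AND S.F is H
IF N is A AND P is H AND K is H THEN R.N is M AND R.P is L AND R.K is L AND S.F is H
IF N is A AND P is H AND K is E THEN R.N is M AND R.P is L AND R.K is L AND S.F is M
IF N is A AND P is E AND K is L THEN R.N is M AND R.P is NIL AND R.K is H AND S.F is L
IF N is A AND P is E AND K is A THEN R.N is M AND R.P is NIL AND R.K is M AND S.F is M
IF N is A AND P is E AND K is H THEN R.N is M AND R.P is NIL AND R.K is L AND S.F is M
IF N is A AND P is E AND K is E THEN R.N is M AND R.P is NIL AND R.K is L AND S.F is M
IF N is H AND P is L AND K is L THEN R.N is L AND R.P is H AND R.K is H AND S.F is L
IF N is H AND P is L AND K is A THEN R.N is L AND R.P is H AND R.K is M AND S.F is L
IF N is H AND P is L AND K is H THEN R.N is L AND R.P is H AND R.K is L AND S.F is L
IF N is H AND P is L AND K is E THEN R.N is L AND R.P is H AND R.K is L AND S.F is L
IF N is H AND P is A AND K is L THEN R.N is L AND R.P is M AND R.K is H AND S.F is L
IF N is H AND P is A AND K is A THEN R.N is L AND R.P is M AND R.K is M AND S.F is H
IF N is H AND P is A AND K is H THEN R.N is L AND R.P is M AND R.K is L AND S.F is H
IF N is H AND P is A AND K is E THEN R.N is L AND R.P is M AND R.K is L AND S.F is M
IF N is H AND P is H AND K is L THEN R.N is L AND R.P is L AND R.K is H AND S.F is L
IF N is H AND P is H AND K is A THEN R.N is L AND R.P is L AND R.K is M AND S.F is H
IF N is H AND P is H AND K is H THEN R.N is L AND R.P is L AND R.K is L AND S.F is H
IF N is H AND P is H AND K is E THEN R.N is L AND R.P is L AND R.K is L AND S.F is M
IF N is H AND P is E AND K is L THEN R.N is L AND R.P is NIL AND R.K is H AND S.F is L
IF N is H AND P is E AND K is A THEN R.N is L AND R.P is NIL AND R.K is M AND S.F is M
IF N is H AND P is E AND K is H THEN R.N is L AND R.P is NIL AND R.K is L AND S.F is M
IF N is H AND P is E AND K is E THEN R.N is L AND R.P is NIL AND R.K is L AND S.F is M
IF N is E AND P is L AND K is L THEN R.N is NIL AND R.P is H AND R.K is H AND S.F is L
IF N is E AND P is L AND K is A THEN R.N is NIL AND R.P is H AND R.K is M AND S.F is L
IF N is E AND P is L AND K is H THEN R.N is NIL AND R.P is H AND R.K is L AND S.F is L
IF N is E AND P is L AND K is E THEN R.N is NIL AND R.P is H AND R.K is L AND S.F is L
IF N is E AND P is A AND K is L THEN R.N is NIL AND R.P is M AND R.K is H AND S.F is L
IF N is E AND P is A AND K is A THEN R.N is NIL AND R.P is M AND R.K is M AND S.F is M
IF N is E AND P is A AND K is H THEN R.N is NIL AND R.P is M AND R.K is L AND S.F is M
IF N is E AND P is A AND K is E THEN R.N is NIL AND R.P is M AND R.K is L AND S.F is M
IF N is E AND P is H AND K is L THEN R.N is NIL AND R.P is L AND R.K is H AND S.F is L
IF N is E AND P is H AND K is A THEN R.N is NIL AND R.P is L AND R.K is M AND S.F is M
IF N is E AND P is H AND K is H THEN R.N is NIL AND R.P is L AND R.K is L AND S.F is M
IF N is E AND P is H AND K is E THEN R.N is NIL AND R.P is L AND R.K is L AND S.F is M
IF N is E AND P is E AND K is L THEN R.N is NIL AND R.P is NIL AND R.K is H AND S.F is L
IF N is E AND P is E AND K is A THEN R.N is NIL AND R.P is NIL AND R.K is M AND S.F is M
IF N is E AND P is E AND K is H THEN R.N is NIL AND R.P is NIL AND R.K is L AND S.F is M
IF N is E AND P is E AND K is E THEN R.N is NIL AND R.P is NIL AND R.K is L AND S.F is M
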