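# Seven-protein worked example network (1-based figure labels).
# Row order introduces nodes 1..7 in sequence (node order is
# first-appearance order).
1	2	+1
3	4	-1
1	4	-1
1	5	+1
5	6	+1
1	7	+1
2	4	+1
2	5	-1
2	7	-1
4	7	-1
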