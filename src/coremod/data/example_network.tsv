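# 22-node worked-example network: a single protein complex {0..9} with core
# {0,1,2,3,4}, peripherals {5,6,7}, overlapping nodes {8,9}, and 12 outside
# nodes {10..21}. All edges weight 0.2 except the high-reliability core edges.
# One concrete reconstruction consistent with every constrained quantity:
#   node 1 incident weights {0.98, 0.87, 0.87, 0.2, 0.2, 0.2} (weighted degree 3.32)
#   node 5: 9 neighbors, 6 inside the complex; node 8: 13 neighbors, 6 inside.
0	1	0.98
0	2	0.9
0	3	0.9
0	4	0.7
1	2	0.87
1	3	0.87
2	3	0.8
2	4	0.8
3	4	0.8
0	5	0.2
0	8	0.2
0	9	0.2
1	5	0.2
1	8	0.2
1	9	0.2
2	5	0.2
2	7	0.2
2	8	0.2
3	5	0.2
3	6	0.2
3	8	0.2
3	9	0.2
4	8	0.2
5	6	0.2
5	7	0.2
6	7	0.2
8	9	0.2
5	10	0.2
5	11	0.2
5	12	0.2
8	10	0.2
8	11	0.2
8	12	0.2
8	13	0.2
8	14	0.2
8	15	0.2
8	16	0.2
9	15	0.2
9	16	0.2
9	17	0.2
9	18	0.2
10	19	0.2
19	20	0.2
19	21	0.2
20	21	0.2
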