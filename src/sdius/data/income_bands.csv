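label,lower,upper,proxy
0-4999,0,4999,
5000-9999,5000,9999,
10000-14999,10000,14999,
15000-19999,15000,19999,
20000-24999,20000,24999,
25000-34999,25000,34999,
35000-44999,35000,44999,
45000-54999,45000,54999,
55000-64999,55000,64999,
65000-74999,65000,74999,
75000-99999,75000,99999,
100000+,100000,,150000
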