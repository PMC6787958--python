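effort,start_time
2,08:00:00
2,23:00:00
5,02:00:00
5,05:00:00
5,06:00:00
5,08:00:00
5,23:00:00
10,00:00:00
10,01:00:00
10,02:00:00
10,06:00:00
10,06:30:00
10,07:00:00
10,07:30:00
10,08:00:00
10,22:00:00
10,23:00:00
20,00:00:00
20,01:00:00
20,02:00:00
20,03:00:00
20,04:00:00
20,05:00:00
20,05:30:00
20,06:00:00
20,06:30:00
20,07:00:00
20,07:30:00
20,08:00:00
20,18:00:00
20,18:30:00
20,19:00:00
20,19:30:00
20,22:00:00
20,22:30:00
20,23:00:00
20,23:30:00
30,00:00:00
30,01:00:00
30,01:30:00
30,02:00:00
30,02:30:00
30,03:00:00
30,03:30:00
30,04:00:00
30,04:30:00
30,05:00:00
30,05:30:00
30,06:00:00
30,06:30:00
30,07:00:00
30,07:30:00
30,08:00:00
30,08:30:00
30,09:00:00
30,09:30:00
30,10:00:00
30,17:00:00
30,17:30:00
30,18:00:00
30,18:30:00
30,19:00:00
30,19:30:00
30,22:00:00
30,22:30:00
30,23:00:00
30,23:30:00
40,00:00:00
40,00:30:00
40,01:00:00
40,01:30:00
40,02:00:00
40,02:30:00
40,03:00:00
40,03:30:00
40,04:00:00
40,04:30:00
40,05:00:00
40,05:30:00
40,05:45:00
40,06:00:00
40,06:15:00
40,06:30:00
40,06:45:00
40,07:00:00
40,07:15:00
40,07:30:00
40,07:45:00
40,08:00:00
40,08:15:00
40,08:30:00
40,08:45:00
40,09:00:00
40,09:30:00
40,10:00:00
40,17:00:00
40,17:30:00
40,18:00:00
40,18:15:00
40,18:30:00
40,18:45:00
40,19:00:00
40,19:30:00
40,22:00:00
40,22:30:00
40,23:00:00
40,23:30:00
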