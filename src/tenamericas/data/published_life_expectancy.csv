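america_id,quantity,mean,lower,upper
1,e0_2000,83.1,82.7,83.5
1,change_2000_2010,2.0,1.8,2.2
1,e0_2010,85.2,84.8,85.5
1,change_2010_2019,0.8,0.7,1.0
1,e0_2019,86.0,85.6,86.3
1,change_2019_2020,-2.2,-2.3,-2.1
1,e0_2020,83.7,83.4,84.1
1,change_2020_2021,0.3,0.2,0.4
1,e0_2021,84.0,83.6,84.4
1,change_2000_2019,2.8,2.6,3.0
1,change_2019_2021,-1.9,-2.1,-1.8
2,e0_2000,80.4,80.1,80.7
2,change_2000_2010,2.3,2.2,2.5
2,e0_2010,82.7,82.4,83.0
2,change_2010_2019,0.3,0.2,0.4
2,e0_2019,83.0,82.8,83.3
2,change_2019_2020,-3.9,-4.0,-3.8
2,e0_2020,79.2,78.9,79.4
2,change_2020_2021,0.3,0.2,0.4
2,e0_2021,79.4,79.2,79.7
2,change_2000_2019,2.6,2.5,2.8
2,change_2019_2021,-3.6,-3.7,-3.5
3,e0_2000,77.5,77.4,77.5
3,change_2000_2010,1.6,1.6,1.6
3,e0_2010,79.1,79.0,79.1
3,change_2010_2019,0.2,0.2,0.2
3,e0_2019,79.3,79.2,79.3
3,change_2019_2020,-1.4,-1.5,-1.4
3,e0_2020,77.9,77.8,77.9
3,change_2020_2021,-0.6,-0.6,-0.6
3,e0_2021,77.2,77.2,77.3
3,change_2000_2019,1.8,1.8,1.8
3,change_2019_2021,-2.0,-2.1,-2.0
4,e0_2000,77.6,77.0,78.1
4,change_2000_2010,1.3,0.6,2.0
4,e0_2010,78.8,78.3,79.4
4,change_2010_2019,-0.2,-1.0,0.5
4,e0_2019,78.6,78.1,79.2
4,change_2019_2020,-1.6,-2.3,-0.8
4,e0_2020,77.0,76.5,77.6
4,change_2020_2021,-0.3,-1.0,0.4
4,e0_2021,76.7,76.2,77.3
4,change_2000_2019,1.0,0.3,1.8
4,change_2019_2021,-1.9,-2.7,-1.1
5,e0_2000,77.8,77.6,78.0
5,change_2000_2010,2.4,2.2,2.5
5,e0_2010,80.1,79.9,80.4
5,change_2010_2019,0.3,0.1,0.4
5,e0_2019,80.4,80.2,80.6
5,change_2019_2020,-3.9,-4.0,-3.8
5,e0_2020,76.5,76.3,76.7
5,change_2020_2021,-0.6,-0.7,-0.4
5,e0_2021,76.0,75.7,76.2
5,change_2000_2019,2.6,2.5,2.8
5,change_2019_2021,-4.5,-4.6,-4.3
6,e0_2000,72.0,71.9,72.1
6,change_2000_2010,3.4,3.3,3.5
6,e0_2010,75.4,75.3,75.5
6,change_2010_2019,0.4,0.3,0.5
6,e0_2019,75.7,75.6,75.8
6,change_2019_2020,-3.0,-3.1,-2.9
6,e0_2020,72.8,72.6,72.9
6,change_2020_2021,-0.5,-0.6,-0.4
6,e0_2021,72.3,72.1,72.4
6,change_2000_2019,3.8,3.7,3.9
6,change_2019_2021,-3.5,-3.6,-3.4
7,e0_2000,70.6,70.5,70.8
7,change_2000_2010,3.7,3.5,3.9
7,e0_2010,74.3,74.2,74.5
7,change_2010_2019,0.5,0.4,0.7
7,e0_2019,74.9,74.7,75.0
7,change_2019_2020,-4.1,-4.2,-3.9
7,e0_2020,70.8,70.7,70.9
7,change_2020_2021,0.7,0.5,0.8
7,e0_2021,71.5,71.3,71.6
7,change_2000_2019,4.2,4.1,4.4
7,change_2019_2021,-3.4,-3.5,-3.2
8,e0_2000,74.8,74.7,74.9
8,change_2000_2010,0.5,0.3,0.6
8,e0_2010,75.3,75.2,75.4
8,change_2010_2019,-0.4,-0.5,-0.3
8,e0_2019,74.8,74.7,74.9
8,change_2019_2020,-2.0,-2.1,-1.9
8,e0_2020,72.8,72.7,72.9
8,change_2020_2021,-1.8,-1.9,-1.6
8,e0_2021,71.1,71.0,71.2
8,change_2000_2019,0.1,-0.1,0.2
8,change_2019_2021,-3.8,-3.9,-3.6
9,e0_2000,70.5,70.3,70.7
9,change_2000_2010,2.3,2.0,2.6
9,e0_2010,72.8,72.6,73.0
9,change_2010_2019,-0.3,-0.6,0.0
9,e0_2019,72.5,72.2,72.7
9,change_2019_2020,-4.0,-4.3,-3.6
9,e0_2020,68.5,68.3,68.7
9,change_2020_2021,-0.5,-0.8,-0.1
9,e0_2021,68.0,67.8,68.3
9,change_2000_2019,2.0,1.6,2.3
9,change_2019_2021,-4.4,-4.7,-4.1
10,e0_2000,72.3,71.0,73.6
10,change_2000_2010,-1.0,-1.5,-0.6
10,e0_2010,71.2,70.0,72.4
10,change_2010_2019,-1.1,-1.5,-0.6
10,e0_2019,70.2,68.9,71.4
10,change_2019_2020,-5.3,-5.8,-4.9
10,e0_2020,64.8,63.7,66.0
10,change_2020_2021,-1.2,-1.7,-0.8
10,e0_2021,63.6,62.3,65.0
10,change_2000_2019,-2.1,-2.6,-1.6
10,change_2019_2021,-6.6,-7.0,-6.1
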